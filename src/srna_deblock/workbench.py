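"""End-to-end pipeline orchestration, report rendering and run manifests.

Sequences the full workflow — simulate (optional) -> preprocess -> annotate
-> profile -> design -> block (optional) -> compare (optional) — from one
structured config, writing every module's outputs plus a manifest that makes
the run reproducible (software version, seed, parameters).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from . import __version__, io
from ._seq import ADAPTER_SEED_LENGTH, DEFAULT_ADAPTER
from .compare import correlation_curve, normalize_pair
from .matcher import annotate_library
from .oligo_design import (
    design_oligos,
    screen_offtargets,
    simulate_blocking,
    write_oligos_fasta,
    write_oligos_tsv,
)
from .preprocess import preprocess_reads, size_class_distribution
from .rrna_profile import find_abundant_fragments, presence_profile, write_fragments_tsv
from .synthetic_data import (
    FIVE_S_NAME,
    PRE_RRNA_NAME,
    SimulationConfig,
    make_references,
    simulate_library,
)

log = logging.getLogger("srna_deblock")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every CLI flag overrides its key here."""

    seed: int = 0
    out_dir: str = "srna_deblock_out"
    # inputs: either simulate (default) or read an existing FASTQ + references
    input_fastq: str | None = None
    reference_fasta: str | None = None
    reference_bed: str | None = None
    simulate: bool = True
    n_reads: int = 50_000
    class_fractions: dict[str, float] | None = None
    error_rate: float = 0.0
    # preprocessing
    adapter: str = DEFAULT_ADAPTER
    sig_len: int = 4
    min_len: int = 18
    max_len: int = 36
    # matching / annotation
    max_mm: int = 0
    # profiling / design
    top_n: int = 7
    min_abundance: int = 10
    frag_min_len: int = 20
    frag_max_len: int = 35
    # blocking / comparison
    block: bool = True
    block_max_mm: int = 2
    compare: bool = True
    exclude_classes: tuple[str, ...] = ("rRNA",)
    offset: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_classes" in data:
            data["exclude_classes"] = tuple(data["exclude_classes"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory report bundle.

    Partial outputs are left in ``out_dir`` when a stage fails; the raised
    error names the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("references")
        if config.reference_fasta and config.reference_bed:
            refs = io.read_reference_set(config.reference_fasta, config.reference_bed)
        else:
            refs = make_references(config.seed)
        refs.write_fasta(out / "references.fasta")
        refs.write_bed(out / "components.bed")
        bundle["refs"] = refs
    except Exception as exc:  # noqa: BLE001
        raise StageError("references", exc) from exc

    try:
        stage("reads")
        if config.input_fastq:
            reads = io.read_sequences(config.input_fastq)
        else:
            fractions = config.class_fractions
            sim_config = SimulationConfig(
                seed=config.seed,
                n_reads=config.n_reads,
                error_rate=config.error_rate,
                adapter_sequence=config.adapter,
                hd_signature_length=config.sig_len,
                **({"class_fractions": dict(fractions)} if fractions else {}),
            )
            sim_reads, ground_truth = simulate_library(sim_config, refs)
            io.write_fastq(sim_reads, out / "simulated.fastq")
            ground_truth.write_tsv(out / "ground_truth.tsv")
            bundle["ground_truth"] = ground_truth
            reads = [r.sequence for r in sim_reads]
        log.info("input reads: %d", len(reads))
    except Exception as exc:  # noqa: BLE001
        raise StageError("reads", exc) from exc

    try:
        stage("preprocess")
        lib, report = preprocess_reads(
            reads,
            adapter_prefix=config.adapter[:ADAPTER_SEED_LENGTH],
            sig_len=config.sig_len,
            min_len=config.min_len,
            max_len=config.max_len,
        )
        log.info(
            "reads %d -> N-filtered %d -> adapter-trimmed %d -> valid %d (NR %d)",
            report.n_input,
            report.n_input - report.n_with_N,
            report.n_adapter_trimmed,
            report.n_valid_inserts,
            lib.NR,
        )
        lib.write_tsv(out / "library.tsv")
        lib.write_fasta(out / "library.fasta")
        report.write_tsv(out / "trim_report.tsv")
        bundle["library"], bundle["trim_report"] = lib, report
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc

    try:
        stage("annotate")
        summary = annotate_library(lib, refs, max_mm=config.max_mm)
        bundle["annotation"] = summary
        bundle["size_classes"] = size_class_distribution(lib)
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", exc) from exc

    try:
        stage("profile")
        profiles = {}
        for name in (PRE_RRNA_NAME, FIVE_S_NAME):
            if name in refs.sequences:
                profiles[name] = presence_profile(lib, refs.sequences[name], name=name)
                profiles[name].write_tsv(out / f"presence_{name}.tsv")
        bundle["profiles"] = profiles

        fragments = []
        for name in profiles:
            fragments.extend(
                find_abundant_fragments(
                    lib,
                    refs.sequences[name],
                    top_n=config.top_n,
                    min_abundance=config.min_abundance,
                    len_range=(config.frag_min_len, config.frag_max_len),
                    name=name,
                )
            )
        write_fragments_tsv(fragments, out / "fragments.tsv")
        bundle["fragments"] = fragments
    except Exception as exc:  # noqa: BLE001
        raise StageError("profile", exc) from exc

    try:
        stage("design")
        oligos = design_oligos(bundle["fragments"])
        write_oligos_tsv(oligos, out / "oligos.tsv")
        write_oligos_fasta(oligos, out / "oligos.fasta")
        offtargets = screen_offtargets(oligos, refs, max_mm=config.max_mm)
        for warning in offtargets:
            log.warning(warning)
        (out / "offtarget_warnings.txt").write_text("\n".join(offtargets) + ("\n" if offtargets else ""))
        bundle["oligos"], bundle["offtargets"] = oligos, offtargets
    except Exception as exc:  # noqa: BLE001
        raise StageError("design", exc) from exc

    if config.block:
        try:
            stage("block")
            blocked_lib, block_report = simulate_blocking(
                lib, bundle["oligos"], max_mm=config.block_max_mm, refs=refs
            )
            blocked_lib.write_tsv(out / "library_blocked.tsv")
            block_report.write_tsv(out / "blocking_report.tsv")
            bundle["blocked_library"], bundle["blocking_report"] = blocked_lib, block_report
            bundle["blocked_annotation"] = annotate_library(blocked_lib, refs, max_mm=config.max_mm)
            for name, profile in bundle["profiles"].items():
                blocked_profile = presence_profile(blocked_lib, refs.sequences[name], name=name)
                blocked_profile.write_tsv(out / f"presence_{name}_blocked.tsv")
                bundle.setdefault("blocked_profiles", {})[name] = blocked_profile
        except Exception as exc:  # noqa: BLE001
            raise StageError("block", exc) from exc

    if config.compare and config.block:
        try:
            stage("compare")
            table = normalize_pair(
                lib,
                bundle["blocked_library"],
                exclude=set(config.exclude_classes),
                refs=refs,
                max_mm=config.max_mm,
                names=("unblocked", "blocked"),
            )
            result = correlation_curve(table, offset=config.offset)
            result.ma.to_csv(out / "ma_points.tsv", sep="\t", index=False)
            result.curve.to_csv(out / "correlation_curve.tsv", sep="\t", index=False)
            bundle["comparison"] = result
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", exc) from exc

    manifest = {
        "package": "srna-deblock",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    render_reports(bundle, out)
    return bundle


def render_reports(bundle: dict, out_dir) -> list[Path]:
    """Write table-style TSVs (3-dp proportions) and figure files."""
    out = Path(out_dir)
    written: list[Path] = []

    for key, fname in (("annotation", "annotation_summary.tsv"), ("blocked_annotation", "annotation_summary_blocked.tsv")):
        if key in bundle:
            table = bundle[key].copy()
            for col in ("complexity", "prop_R", "prop_NR"):
                table[col] = table[col].map(lambda x: f"{x:.3f}")
            path = out / fname
            table.to_csv(path, sep="\t", index=False)
            written.append(path)

    if "size_classes" in bundle:
        dist = bundle["size_classes"]
        path = out / "size_classes.tsv"
        dist.to_csv(path, sep="\t", index=False)
        written.append(path)
        if len(dist):
            fig, ax = plt.subplots(figsize=(6, 3.5))
            ax.bar(dist["length"], dist["R"], color="0.4")
            ax.set_xlabel("insert length (nt)")
            ax.set_ylabel("redundant reads")
            ax.set_title("size-class distribution")
            fig.tight_layout()
            fig.savefig(out / "size_classes.png", dpi=120)
            plt.close(fig)
            written.append(out / "size_classes.png")

    oligos = bundle.get("oligos", [])
    for key, suffix in (("profiles", ""), ("blocked_profiles", "_blocked")):
        for name, profile in bundle.get(key, {}).items():
            fig, ax = plt.subplots(figsize=(7, 3))
            ax.plot(profile.values, lw=0.8, color="tab:blue")
            for i, oligo in enumerate(o for o in oligos if o.target_transcript == name):
                ax.axvspan(oligo.target_start, oligo.target_end, color="tab:red", alpha=0.25)
                ax.text(oligo.target_start, ax.get_ylim()[1] * 0.95, str(i + 1), fontsize=7)
            ax.set_xlim(0, len(profile.values))
            ax.set_xlabel(f"position on {name}")
            ax.set_ylabel("presence (linear)")
            fig.tight_layout()
            path = out / f"presence_{name}{suffix}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

    if "comparison" in bundle:
        ma = bundle["comparison"].ma
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(ma["A"], ma["M"], s=6, alpha=0.5, edgecolors="none")
        ax.axhline(0, color="0.3", lw=0.8)
        ax.set_xlabel("A (mean log2 RPM)")
        ax.set_ylabel("M (log2 ratio)")
        fig.tight_layout()
        fig.savefig(out / "ma_plot.png", dpi=120)
        plt.close(fig)
        written.append(out / "ma_plot.png")
    return written
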