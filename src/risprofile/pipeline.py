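"""End-to-end orchestration: config, reference loading, and the full profile run.

`run_profile` drives alignment records (or pre-called sites) through site
calling, annotation, enrichment against a fresh random control, hotspot and
clonality analyses, writing one TSV per stage plus a provenance record.
Every default in :class:`RunConfig` is the analysis' standard rule set, so a
bare run applies the canonical thresholds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import annotate as _annotate
from . import enrichment as _enrichment
from . import hotspots as _hotspots
from .clonality import capture_frequencies, write_clonality_tsv
from .reads import Read, merge_read_pair, naive_locate, truncate_by_quality
from .reference import (
    ReferenceBundle,
    read_bed,
    read_chrom_sizes,
    read_gene_list,
    read_gene_table,
    read_narrowpeak,
    read_repeat_table,
)
from .sites import (
    IntegrationSite,
    call_sites,
    read_alignment_sam,
    read_alignment_tsv,
    read_sites_tsv,
    write_sites_bed,
    write_sites_tsv,
)


@dataclass
class RunConfig:
    """All inputs and thresholds for a profile run.

    Threshold defaults: Q<27 / 3rd low base truncation; ambiguity at >95%
    of best score (>90% below score 100); TSS <10 kb; CpG <=1 kb; peak
    proximity <=50 kb; centromere <1 Mbp; oncogene TSS <50/<500 kb; 10
    strength deciles; hotspots of >=3 sites in 5/50 kb windows over matched
    subsets; clonality threshold 1%; random control of 10,000 sites.
    """

    # inputs
    alignments: str | None = None          # TSV or SAM of candidate placements
    sites: str | None = None               # pre-called sites TSV (alternative)
    chrom_sizes: str = ""
    genes: str = ""
    oncogenes: str | None = None
    cpg_islands: str | None = None
    repeats: str | None = None
    centromeres: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)   # mark -> narrowPeak
    use_signal_value: bool = False
    # read preprocessing
    q_threshold: int = 27
    nth_low: int = 3
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    # ambiguity rule
    ambiguity_ratio: float = 0.95
    ambiguity_low_ratio: float = 0.90
    ambiguity_score_cutoff: float = 100
    # annotation thresholds
    tss_kb: float = 10
    cpg_kb: float = 1
    near_kb: float = 50
    centromere_mb: float = 1
    onco_kb: tuple[float, float] = (50, 500)
    n_bins: int = 10
    # hotspots
    hotspot_windows_kb: tuple[float, ...] = (5, 50)
    hotspot_min_sites: int = 3
    subset_size: int = 320
    min_subsets: int = 3
    # clonality / control
    clonality_threshold: float = 0.01
    random_n: int = 10_000
    seed: int = 0
    outdir: str = "risprofile_out"

    def __post_init__(self) -> None:
        positive = {
            "q_threshold": self.q_threshold, "nth_low": self.nth_low,
            "tss_kb": self.tss_kb, "cpg_kb": self.cpg_kb, "near_kb": self.near_kb,
            "centromere_mb": self.centromere_mb, "n_bins": self.n_bins,
            "subset_size": self.subset_size, "random_n": self.random_n,
            "clonality_threshold": self.clonality_threshold,
            "hotspot_min_sites": self.hotspot_min_sites,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"config threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "onco_kb" in data:
            data["onco_kb"] = tuple(data["onco_kb"])
        if "hotspot_windows_kb" in data:
            data["hotspot_windows_kb"] = tuple(data["hotspot_windows_kb"])
        return cls(**data)


def load_reference(config: RunConfig) -> ReferenceBundle:
    layout = read_chrom_sizes(config.chrom_sizes)
    oncogene_names = read_gene_list(config.oncogenes) if config.oncogenes else set()
    genes = read_gene_table(config.genes, oncogene_names) if config.genes else []
    cpg = read_bed(config.cpg_islands) if config.cpg_islands else []
    repeats = read_repeat_table(config.repeats) if config.repeats else []
    centromeres = read_bed(config.centromeres) if config.centromeres else []
    peak_sets = {
        mark: read_narrowpeak(path, use_signal_value=config.use_signal_value)
        for mark, path in config.peaks.items()
    }
    return ReferenceBundle(
        layout=layout, genes=genes, cpg_islands=cpg, repeats=repeats,
        centromeres=centromeres, peak_sets=peak_sets,
        oncogene_names=oncogene_names,
    )


# ---------------------------------------------------------------------------
# read-level pipeline (synthetic end-to-end path)


def preprocess_pairs(
    pairs: Iterable[tuple[Read, Read]],
    q_threshold: int = 27,
    nth_low: int = 3,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> list[Read]:
    """Merge pairs and quality-truncate; unmergeable pairs are dropped."""
    out = []
    for fwd, rev in pairs:
        merged = merge_read_pair(fwd, rev, min_overlap, max_mismatch_rate)
        if merged is None:
            continue
        truncated = truncate_by_quality(merged, q_threshold, nth_low)
        if len(truncated) > 0:
            out.append(truncated)
    return out


def process_read_pairs(
    pairs: Iterable[tuple[Read, Read]],
    sequences: dict[str, str],
    min_score: int = 40,
    config: RunConfig | None = None,
) -> list[IntegrationSite]:
    """Full synthetic path: merge, truncate, place naively, call sites."""
    config = config or RunConfig()
    reads = preprocess_pairs(
        pairs, config.q_threshold, config.nth_low,
        config.min_overlap, config.max_mismatch_rate,
    )
    records = []
    for read in reads:
        records.extend(naive_locate(read, sequences, min_score=min_score))
    return call_sites(
        records, config.ambiguity_ratio, config.ambiguity_low_ratio,
        config.ambiguity_score_cutoff,
    )


# ---------------------------------------------------------------------------
# full profile run


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_ENRICH_CATEGORIES = (
    "in_gene", "tss_lt_kb", "cpg", "onco_lt_near_kb", "onco_lt_far_kb",
    "centromere", "repeat:Satellite",
)


def run_profile(config: RunConfig) -> Path:
    """Run the whole profile and write per-stage TSVs under ``config.outdir``."""
    input_paths = [
        p for p in (
            config.alignments, config.sites, config.chrom_sizes, config.genes,
            config.oncogenes, config.cpg_islands, config.repeats,
            config.centromeres, *config.peaks.values(),
        ) if p
    ]
    missing = [p for p in input_paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {', '.join(missing)}")
    if config.alignments is None and config.sites is None:
        raise ValueError("config must name either alignments or sites")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = load_reference(config)

    if config.sites is not None:
        sites = read_sites_tsv(config.sites)
    else:
        path = Path(config.alignments)
        records = (
            read_alignment_sam(path) if path.suffix.lower() == ".sam"
            else read_alignment_tsv(path)
        )
        sites = call_sites(
            records, config.ambiguity_ratio, config.ambiguity_low_ratio,
            config.ambiguity_score_cutoff,
        )
    write_sites_tsv(sites, outdir / "sites.tsv")
    write_sites_bed(sites, outdir / "sites.bed")

    annotator = _annotate.Annotator(
        reference, near_kb=config.near_kb, tss_kb=config.tss_kb,
        cpg_kb=config.cpg_kb, centromere_mb=config.centromere_mb,
        onco_kb=config.onco_kb, n_bins=config.n_bins,
    )
    annotations = annotator.annotate(sites)
    _annotate.write_annotations_tsv(annotations, outdir / "annotations.tsv")
    summary = _annotate.summarize_profile(
        annotations, tss_kb=config.tss_kb, onco_kb=config.onco_kb,
        near_kb=config.near_kb,
    )

    rng = np.random.default_rng(config.seed)
    random_sites = _enrichment.sample_random_sites(
        config.random_n, reference.layout, rng
    )
    random_summary = _annotate.summarize_profile(
        annotator.annotate(random_sites), tss_kb=config.tss_kb,
        onco_kb=config.onco_kb, near_kb=config.near_kb,
    )
    _annotate.write_summary_tsv(
        {"sample": summary, "random": random_summary}, outdir / "summary.tsv"
    )
    _annotate.write_histogram_tsv(summary, outdir / "histograms.tsv")

    results = {}
    categories = list(_ENRICH_CATEGORIES) + [
        f"near_peak:{mark}" for mark in reference.peak_sets
    ]
    for cat in categories:
        if cat not in summary.counts:
            continue
        try:
            results[cat] = _enrichment.compare_profiles(summary, random_summary, cat)
        except ValueError:
            continue  # degenerate control proportion; category not testable
    _enrichment.write_enrichment_tsv(results, outdir / "enrichment.tsv")

    unambiguous = [s for s in sites if not s.ambiguous]
    hotspot_results = []
    if len(unambiguous) >= config.subset_size * config.min_subsets:
        mark = next(iter(reference.peak_sets), None)
        peaks = reference.peak_sets.get(mark, []) if mark else None
        for window_kb in config.hotspot_windows_kb:
            hotspot_results.append(
                _hotspots.hotspot_analysis(
                    unambiguous, k=config.subset_size,
                    window_bp=int(window_kb * 1000),
                    min_sites=config.hotspot_min_sites,
                    min_subsets=config.min_subsets,
                    seed=np.random.default_rng(config.seed),
                    peaks=peaks or None, near_kb=config.near_kb,
                )
            )
    _hotspots.write_hotspot_tsv(hotspot_results, outdir / "hotspots.tsv")

    clonality = capture_frequencies(sites, threshold=config.clonality_threshold)
    write_clonality_tsv(clonality, outdir / "clonality.tsv")

    provenance = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "input_checksums": {p: _md5(p) for p in input_paths},
        "n_sites": len(sites),
        "n_unambiguous": len(unambiguous),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return outdir
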