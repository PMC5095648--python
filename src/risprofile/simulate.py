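"""Synthetic genomes, integration-site mixtures, and junction reads.

The generator emulates the structure of the real inputs — a genome layout
with genes, CpG islands, repeats, centromeres and scored heterochromatin
(H3K9me3-style) peaks — plus integration-site sets drawn from a tethering
mixture, so that every pipeline stage has a ground-truth oracle.

Built-in structure, chosen to mirror the biology the pipeline measures:

- satellite repeat blocks flank each centromere (pericentromeric
  heterochromatin), so satellite placement and centromere proximity are
  coupled;
- genes (and hence TSSs, CpG islands and proto-oncogenes) avoid the
  pericentromeric zone;
- peaks in the pericentromeric zone receive boosted strengths, so the
  strongest decile bin is a gene-poor, centromere-proximal set — the
  defining property of strong heterochromatin peaks.

An integration-site set is a three-component mixture: with probability
``pi_peak`` a site falls within ``d_peak`` of a random strongest-bin peak,
with ``pi_sat`` uniformly inside a satellite block, otherwise uniformly over
the genome (optionally biased toward genes, modelling the mild gene
preference of an unmodified foamy-virus vector). Mixture weights are
simulator parameters, not estimates of any real data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import _FeatureArrays, assign_strength_bins
from .enrichment import sample_random_sites
from .reads import Read, revcomp, write_fasta, write_fastq
from .reference import (
    GenomeLayout,
    GenomicInterval,
    GeneModel,
    Peak,
    ReferenceBundle,
    RepeatFeature,
)
from .sites import IntegrationSite


@dataclass
class ReferenceConfig:
    """Layout of the synthetic genome; defaults give a 3 x 10 Mb genome."""

    n_chroms: int = 3
    chrom_length: int = 10_000_000
    centromere_halfwidth: int = 50_000
    pericentromeric_halfwidth: int = 600_000
    n_satellites_per_chrom: int = 20
    satellite_length: int = 25_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (5_000, 60_000)
    n_oncogenes: int = 30
    n_cpg: int = 200
    cpg_length: int = 1_000
    cpg_near_tss_fraction: float = 0.7
    repeat_counts: dict[str, int] = field(
        default_factory=lambda: {"LINE": 150, "SINE": 150, "LTR": 60, "DNA": 60,
                                 "Other": 20}
    )
    repeat_length_range: tuple[int, int] = (500, 5_000)
    n_peaks: int = 200
    peak_length_range: tuple[int, int] = (2_000, 8_000)
    pericentromeric_peak_fraction: float = 0.3
    pericentromeric_strength_boost: float = 8.0
    peak_gene_avoidance: float = 0.8
    mark: str = "H3K9me3"
    with_sequence: bool = False
    n_decoys: int = 0
    decoy_length: int = 2_000


@dataclass
class SyntheticReference:
    bundle: ReferenceBundle
    sequences: dict[str, str] | None = None
    decoys: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)


def _check_feasible(config: ReferenceConfig) -> None:
    peri = config.pericentromeric_halfwidth - config.centromere_halfwidth
    sat_span = (config.n_satellites_per_chrom // 2 + 1) * config.satellite_length
    if sat_span > peri:
        raise ValueError(
            "infeasible packing: satellite blocks do not fit in the "
            "pericentromeric zone"
        )
    if config.gene_length_range[1] >= config.chrom_length // 4:
        raise ValueError("infeasible packing: genes too long for chromosome")
    if 2 * config.pericentromeric_halfwidth >= config.chrom_length:
        raise ValueError("infeasible packing: pericentromeric zone exceeds chromosome")


def generate_reference(
    config: ReferenceConfig | None = None, seed: int | np.random.Generator = 0
) -> SyntheticReference:
    """Build a deterministic synthetic :class:`ReferenceBundle` (+ sequence)."""
    config = config or ReferenceConfig()
    _check_feasible(config)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = config.chrom_length
    chroms = [(f"chr{i + 1}", L) for i in range(config.n_chroms)]
    layout = GenomeLayout(chroms)

    centromeres: list[GenomicInterval] = []
    satellites: list[RepeatFeature] = []
    peri_zones: dict[str, tuple[int, int]] = {}
    for chrom, _ in chroms:
        mid = L // 2
        centromeres.append(
            GenomicInterval(chrom, mid - config.centromere_halfwidth,
                            mid + config.centromere_halfwidth)
        )
        peri_zones[chrom] = (mid - config.pericentromeric_halfwidth,
                             mid + config.pericentromeric_halfwidth)
        # tile satellite blocks outward from the centromere on both sides
        n_left = config.n_satellites_per_chrom // 2
        n_right = config.n_satellites_per_chrom - n_left
        slen = config.satellite_length
        cursor = mid - config.centromere_halfwidth
        for _ in range(n_left):
            gap = int(rng.integers(0, slen // 4))
            cursor -= gap + slen
            satellites.append(
                RepeatFeature(GenomicInterval(chrom, cursor, cursor + slen), "Satellite")
            )
        cursor = mid + config.centromere_halfwidth
        for _ in range(n_right):
            gap = int(rng.integers(0, slen // 4))
            satellites.append(
                RepeatFeature(
                    GenomicInterval(chrom, cursor + gap, cursor + gap + slen),
                    "Satellite",
                )
            )
            cursor += gap + slen

    def outside_peri(chrom: str, start: int, end: int) -> bool:
        lo, hi = peri_zones[chrom]
        return end <= lo or start >= hi

    # genes avoid the pericentromeric zone entirely
    genes: list[GeneModel] = []
    onco_idx = set(
        rng.choice(config.n_genes, size=config.n_oncogenes, replace=False).tolist()
    )
    for i in range(config.n_genes):
        while True:
            chrom = chroms[int(rng.integers(config.n_chroms))][0]
            glen = int(rng.integers(*config.gene_length_range))
            start = int(rng.integers(0, L - glen))
            if outside_peri(chrom, start, start + glen):
                break
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"GENE{i:04d}"
        iv = GenomicInterval(chrom, start, start + glen, strand, name)
        tss = start if strand == "+" else start + glen - 1
        genes.append(GeneModel(name, iv, tss, is_oncogene=i in onco_idx))
    oncogene_names = {g.name for g in genes if g.is_oncogene}

    # CpG islands: mostly promoter-associated, remainder uniform
    cpg: list[GenomicInterval] = []
    for _ in range(config.n_cpg):
        if rng.random() < config.cpg_near_tss_fraction:
            g = genes[int(rng.integers(len(genes)))]
            center = g.tss + int(rng.integers(-2_000, 2_000))
            chrom = g.interval.chrom
        else:
            chrom = chroms[int(rng.integers(config.n_chroms))][0]
            center = int(rng.integers(config.cpg_length, L - config.cpg_length))
        start = max(0, min(center - config.cpg_length // 2, L - config.cpg_length))
        cpg.append(GenomicInterval(chrom, start, start + config.cpg_length))

    # interspersed repeats, uniform
    repeats: list[RepeatFeature] = list(satellites)
    for cls, count in config.repeat_counts.items():
        for _ in range(count):
            chrom = chroms[int(rng.integers(config.n_chroms))][0]
            rlen = int(rng.integers(*config.repeat_length_range))
            start = int(rng.integers(0, L - rlen))
            repeats.append(RepeatFeature(GenomicInterval(chrom, start, start + rlen), cls))

    # peaks: heavy-tailed strengths; pericentromeric peaks boosted
    gene_arrays = _FeatureArrays(g.interval for g in genes)
    peaks: list[Peak] = []
    for i in range(config.n_peaks):
        plen = int(rng.integers(*config.peak_length_range))
        pericentromeric = rng.random() < config.pericentromeric_peak_fraction
        while True:
            chrom = chroms[int(rng.integers(config.n_chroms))][0]
            if pericentromeric:
                lo, hi = peri_zones[chrom]
                start = int(rng.integers(lo, hi - plen))
                break
            start = int(rng.integers(0, L - plen))
            in_gene = gene_arrays.distances(
                chrom, np.array([start + plen // 2])
            )[0] == 0
            if not in_gene or rng.random() > config.peak_gene_avoidance:
                break
        strength = float(rng.lognormal(mean=3.0, sigma=1.0))
        if pericentromeric:
            strength *= config.pericentromeric_strength_boost
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + plen, name=f"peak{i:04d}"),
                 strength)
        )

    sequences = None
    decoys: list[tuple[GenomicInterval, GenomicInterval]] = []
    if config.with_sequence:
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences = {
            chrom: base_codes[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            for chrom, length in chroms
        }
        for _ in range(config.n_decoys):
            dlen = config.decoy_length
            src_chrom = chroms[0][0]
            dst_chrom = chroms[-1][0] if config.n_chroms > 1 else src_chrom
            a = int(rng.integers(0, L - dlen))
            b = int(rng.integers(0, L - dlen))
            seq = sequences[src_chrom][a:a + dlen]
            s = sequences[dst_chrom]
            sequences[dst_chrom] = s[:b] + seq + s[b + dlen:]
            decoys.append(
                (GenomicInterval(src_chrom, a, a + dlen),
                 GenomicInterval(dst_chrom, b, b + dlen))
            )

    bundle = ReferenceBundle(
        layout=layout,
        genes=genes,
        cpg_islands=cpg,
        repeats=repeats,
        centromeres=centromeres,
        peak_sets={config.mark: peaks},
        oncogene_names=oncogene_names,
    )
    return SyntheticReference(bundle=bundle, sequences=sequences, decoys=decoys)


# ---------------------------------------------------------------------------
# integration-site mixture


@dataclass
class TetherModel:
    """Mixture weights for site placement.

    ``pi_peak``: probability of placement within ``d_peak`` bp of a random
    strongest-bin peak; ``pi_sat``: probability of uniform placement inside a
    satellite block; the rest is genome-wide background, optionally weighted
    toward gene bodies by ``gene_bias`` (>1 favours genes).
    """

    pi_peak: float = 0.0
    pi_sat: float = 0.0
    d_peak: int = 10_000
    gene_bias: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.pi_peak <= 1 and 0 <= self.pi_sat <= 1):
            raise ValueError("mixture weights must lie in [0, 1]")
        if self.pi_peak + self.pi_sat > 1:
            raise ValueError("pi_peak + pi_sat must not exceed 1")
        if self.gene_bias <= 0:
            raise ValueError("gene_bias must be positive")

    @classmethod
    def control(cls) -> "TetherModel":
        """Unmodified-vector conditions: no tethering, mild gene preference."""
        return cls(pi_peak=0.0, pi_sat=0.0, gene_bias=1.5)

    @classmethod
    def retargeted(cls) -> "TetherModel":
        """Heterochromatin-retargeted conditions."""
        return cls(pi_peak=0.35, pi_sat=0.3)


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for a simulated site set."""

    labels: list[str]                     # per site: peak / satellite / background
    component_counts: dict[str, int]
    read_counts: list[int]

    @property
    def total_reads(self) -> int:
        return sum(self.read_counts)


def _background_positions(
    n: int,
    layout: GenomeLayout,
    gene_arrays: _FeatureArrays,
    gene_bias: float,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Uniform background, with gene bodies weighted by ``gene_bias``."""
    out: list[tuple[str, int]] = []
    hi = max(gene_bias, 1.0)
    while len(out) < n:
        batch = sample_random_sites(max(2 * (n - len(out)), 64), layout, rng)
        for s in batch:
            in_gene = gene_arrays.distances(
                s.chrom, np.array([s.position])
            )[0] == 0
            weight = gene_bias if in_gene else 1.0
            if rng.random() < weight / hi:
                out.append((s.chrom, s.position))
                if len(out) == n:
                    break
    return out


def simulate_sites(
    model: TetherModel,
    reference: ReferenceBundle | SyntheticReference,
    n_sites: int,
    clone_count_distribution: tuple[str, float] | Sequence[int] | None = None,
    seed: int | np.random.Generator = 0,
    edge_margin: int = 0,
    mark: str | None = None,
) -> tuple[list[IntegrationSite], SyntheticTruth]:
    """Draw ``n_sites`` integration sites from the tethering mixture.

    ``clone_count_distribution``: ``None`` for one read per site,
    ``("logseries", p)`` for log-series clone sizes, or an explicit
    per-site count sequence. ``edge_margin`` keeps sites away from
    chromosome ends so junction reads can be simulated around them.
    """
    bundle = reference.bundle if isinstance(reference, SyntheticReference) else reference
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mark = mark or next(iter(bundle.peak_sets), None)

    strong_peaks: list[Peak] = []
    if model.pi_peak > 0:
        peaks = bundle.peak_sets.get(mark or "", [])
        if not peaks:
            raise ValueError("pi_peak > 0 but the reference has no peaks")
        if all(p.bin is None for p in peaks):
            peaks = assign_strength_bins(peaks)
        top = max(p.bin for p in peaks)
        strong_peaks = [p for p in peaks if p.bin == top]
    satellites = bundle.satellites
    if model.pi_sat > 0 and not satellites:
        raise ValueError("pi_sat > 0 but the reference has no satellite repeats")
    sat_lengths = np.array([len(s.interval) for s in satellites], dtype=float)
    sat_weights = sat_lengths / sat_lengths.sum() if len(satellites) else None

    gene_arrays = _FeatureArrays(g.interval for g in bundle.genes)
    u = rng.random(n_sites)
    labels = np.where(
        u < model.pi_peak, "peak",
        np.where(u < model.pi_peak + model.pi_sat, "satellite", "background"),
    )
    n_background = int(np.sum(labels == "background"))
    background = iter(
        _background_positions(
            n_background, bundle.layout, gene_arrays, model.gene_bias, rng
        )
    )

    sites: list[IntegrationSite] = []
    if clone_count_distribution is None:
        counts = [1] * n_sites
    elif isinstance(clone_count_distribution, tuple):
        kind, p = clone_count_distribution
        if kind != "logseries":
            raise ValueError(f"unknown clone count distribution {kind!r}")
        counts = [int(c) for c in rng.logseries(p, size=n_sites)]
    else:
        counts = [int(c) for c in clone_count_distribution]
        if len(counts) != n_sites:
            raise ValueError("clone count sequence length != n_sites")

    for label, count in zip(labels, counts):
        if label == "peak":
            pk = strong_peaks[int(rng.integers(len(strong_peaks)))]
            iv = pk.interval
            lo = iv.start - model.d_peak
            hi = iv.end + model.d_peak
            chrom = iv.chrom
            pos = int(rng.integers(lo, hi))
        elif label == "satellite":
            s = satellites[int(rng.choice(len(satellites), p=sat_weights))]
            chrom = s.interval.chrom
            pos = int(rng.integers(s.interval.start, s.interval.end))
        else:
            chrom, pos = next(background)
        chrom_len = bundle.layout.lengths[chrom]
        pos = max(edge_margin, min(pos, chrom_len - 1 - edge_margin))
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(IntegrationSite(chrom, pos, strand, read_count=count))

    label_list = [str(l) for l in labels]
    truth = SyntheticTruth(
        labels=label_list,
        component_counts={
            c: label_list.count(c) for c in ("peak", "satellite", "background")
        },
        read_counts=counts,
    )
    return sites, truth


# ---------------------------------------------------------------------------
# junction reads


def simulate_reads(
    sites: Sequence[IntegrationSite],
    sequences: dict[str, str],
    read_length: int = 100,
    template_length: int = 150,
    error_rate: float = 0.0,
    base_quality: int = 38,
    lowq_tail_start: int | None = None,
    lowq_quality: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[Read, Read]], list[int]]:
    """Simulate junction read pairs; returns (pairs, per-read site index).

    The template starts at the junction base and runs 3' into the genome on
    the site's strand; the forward read is its head, the reverse read the
    reverse complement of its tail, so merging reconstructs the template.
    ``site.read_count`` pairs are emitted per site. Substitution errors are
    applied per read at ``error_rate``; an optional low-quality tail
    (``lowq_tail_start`` onward at ``lowq_quality``) exercises quality
    truncation downstream.
    """
    if read_length > template_length:
        raise ValueError("read_length must not exceed template_length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs: list[tuple[Read, Read]] = []
    origins: list[int] = []
    for si, site in enumerate(sites):
        seq = sequences.get(site.chrom)
        if seq is None:
            raise ValueError(f"no sequence for chromosome {site.chrom}")
        if template_length > len(seq):
            raise ValueError("read template exceeds chromosome length")
        p = site.position
        if site.strand == "+":
            if p + template_length > len(seq):
                raise ValueError(
                    f"site {site.chrom}:{p} too close to chromosome end"
                )
            template = seq[p:p + template_length]
        else:
            if p - template_length + 1 < 0:
                raise ValueError(
                    f"site {site.chrom}:{p} too close to chromosome start"
                )
            template = revcomp(seq[p - template_length + 1:p + 1])
        for ri in range(site.read_count):
            rid = f"site{si:05d}_read{ri:03d}"
            fwd_bases = _mutate(template[:read_length], error_rate, rng)
            rev_bases = _mutate(revcomp(template)[:read_length], error_rate, rng)
            quals = [base_quality] * read_length
            if lowq_tail_start is not None:
                quals = (
                    [base_quality] * min(lowq_tail_start, read_length)
                    + [lowq_quality] * max(0, read_length - lowq_tail_start)
                )
            pairs.append(
                (Read(rid, fwd_bases, tuple(quals)),
                 Read(rid, rev_bases, tuple(quals)))
            )
            origins.append(si)
    return pairs, origins


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    bases = list(seq)
    hits = np.flatnonzero(rng.random(len(bases)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != bases[i]]
        bases[i] = choices[int(rng.integers(3))]
    return "".join(bases)


# ---------------------------------------------------------------------------
# file emission (the exact formats the pipeline parsers read)


def write_reference_files(
    reference: SyntheticReference, outdir: str | Path
) -> dict[str, Path]:
    """Write the bundle to disk in the standard input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = reference.bundle
    paths: dict[str, Path] = {}

    p = outdir / "chrom.sizes"
    with open(p, "w") as fh:
        for chrom, length in bundle.layout.chroms:
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = p

    p = outdir / "genes.tsv"
    with open(p, "w") as fh:
        for g in bundle.genes:
            iv = g.interval
            fh.write(f"{g.name}\t{iv.chrom}\t{iv.strand}\t{iv.start}\t{iv.end}\n")
    paths["genes"] = p

    p = outdir / "oncogenes.txt"
    with open(p, "w") as fh:
        for name in sorted(bundle.oncogene_names):
            fh.write(name + "\n")
    paths["oncogenes"] = p

    p = outdir / "cpg_islands.bed"
    with open(p, "w") as fh:
        for iv in bundle.cpg_islands:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    paths["cpg"] = p

    p = outdir / "centromeres.bed"
    with open(p, "w") as fh:
        for iv in bundle.centromeres:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    paths["centromeres"] = p

    p = outdir / "repeats.tsv"
    with open(p, "w") as fh:
        for r in bundle.repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_class}\n")
    paths["repeats"] = p

    for mark, peaks in bundle.peak_sets.items():
        p = outdir / f"{mark}.narrowPeak"
        with open(p, "w") as fh:
            for pk in peaks:
                iv = pk.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{pk.strength:g}\t.\t{pk.strength:g}\t-1\t-1\t-1\n"
                )
        paths[f"peaks_{mark}"] = p

    if reference.sequences is not None:
        p = outdir / "genome.fa"
        write_fasta(reference.sequences, p)
        paths["fasta"] = p
    return paths
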