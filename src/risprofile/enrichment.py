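"""Random-site controls and chi-square goodness-of-fit enrichment tests.

The comparison baseline is a set of uniformly random genomic positions
(classically 10,000 sites). Feature enrichment of an observed site set is
tested by a chi-square goodness-of-fit: the control set supplies the
expected category proportions, the test set the observed counts. The test
conditions on the expected proportions being known — it is well calibrated
when the control is much larger than the test set (or exact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .annotate import ProfileSummary
from .reference import GenomeLayout
from .sites import IntegrationSite

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class EnrichmentResult:
    """Chi-square goodness-of-fit of observed counts against control proportions."""

    categories: list[str]
    observed: list[int]
    expected: list[float]
    statistic: float
    df: int
    p_value: float

    @property
    def stars(self) -> str:
        return "*" * sum(self.p_value < a for a in SIGNIFICANCE_LEVELS)


def sample_random_sites(
    n: int,
    layout: GenomeLayout,
    seed: int | np.random.Generator = 0,
) -> list[IntegrationSite]:
    """Draw ``n`` uniform random sites over the mappable genome.

    Positions are uniform over the unmasked genome (sampled with
    replacement; base-pair collisions are allowed), strand uniform over
    {+, -}, read_count 1. Deterministic under a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    segments = layout.mappable_segments()
    if not segments:
        raise ValueError("genome layout has no mappable sequence")
    lengths = np.array([len(s) for s in segments], dtype=np.int64)
    cum = np.cumsum(lengths)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=n)
    seg_idx = np.searchsorted(cum, draws, side="right")
    offsets = draws - (cum[seg_idx] - lengths[seg_idx])
    strands = rng.choice(["+", "-"], size=n)
    return [
        IntegrationSite(segments[i].chrom, int(segments[i].start + off), str(st))
        for i, off, st in zip(seg_idx, offsets, strands)
    ]


def chisq_gof(
    observed: Sequence[int],
    expected_props: Sequence[float],
    categories: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Chi-square goodness-of-fit of counts against fixed expected proportions.

    ``statistic = sum (O_i - E_i)^2 / E_i`` with ``E_i = N * p_i`` and
    ``df = k - 1``; the p-value is the upper chi-square tail.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected_props must be 1-D of equal length >= 2")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {props.sum()}, not 1")
    total = obs.sum()
    expected = total * props
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count in a category; merge sparse categories first"
        )
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    p = float(_chi2_dist.sf(stat, df))
    cats = list(categories) if categories else [f"cat{i}" for i in range(len(obs))]
    return EnrichmentResult(
        categories=cats,
        observed=[int(o) for o in obs],
        expected=[float(e) for e in expected],
        statistic=stat,
        df=df,
        p_value=p,
    )


def compare_counts(
    test_count: int,
    test_total: int,
    control_count: int,
    control_total: int,
    category: str = "in_category",
) -> EnrichmentResult:
    """Binary GOF: test in/out counts vs control-derived proportions."""
    p = control_count / control_total
    if p <= 0 or p >= 1:
        raise ValueError(
            f"control proportion {p} for {category!r} is degenerate; "
            "a binary GOF needs 0 < p < 1"
        )
    return chisq_gof(
        [test_count, test_total - test_count],
        [p, 1 - p],
        categories=[category, f"not_{category}"],
    )


def compare_profiles(
    test: ProfileSummary,
    control: ProfileSummary,
    category: str,
) -> EnrichmentResult:
    """Compare one summary category between a test and a control site set.

    The control summary defines the expected in/out proportions; the test
    set's counts are the observations.
    """
    for summ, which in ((test, "test"), (control, "control")):
        if category not in summ.counts:
            raise ValueError(f"category {category!r} missing from {which} summary")
    return compare_counts(
        test.counts[category],
        test.denominators[category],
        control.counts[category],
        control.denominators[category],
        category=category,
    )


def compare_binned(
    test_counts: Sequence[int],
    control_counts: Sequence[int],
    categories: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Multi-bin GOF (e.g. per-decile peak proximity) against control proportions."""
    control = np.asarray(control_counts, dtype=float)
    if np.any(control <= 0):
        raise ValueError("every control bin must be non-empty; merge bins first")
    return chisq_gof(test_counts, control / control.sum(), categories)


def write_enrichment_tsv(results: dict[str, EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("#category\tobserved\texpected\tchi2\tdf\tp_value\tstars\n")
        for name, r in results.items():
            fh.write(
                f"{name}\t{','.join(map(str, r.observed))}\t"
                f"{','.join(f'{e:.2f}' for e in r.expected)}\t"
                f"{r.statistic:.4f}\t{r.df}\t{r.p_value:.4g}\t{r.stars}\n"
            )
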