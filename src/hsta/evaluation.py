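"""Pipeline-evaluation statistics against a known mock community.

Given the abundance table a classifier produces and the expected community
(taxa with measured biomass), three summaries describe how well the
pipeline did:

* detection ratio — the fraction of expected taxa that received any reads;
* biomass correlation — Pearson's r between per-taxon read counts and
  biomass, computed only when more than one expected taxon was detected;
* species-pair count ratios — for a chosen pair (e.g. the heaviest vs. a
  light carabid), the read-count ratio per strand and its arithmetic mean,
  used to gauge amplification bias against the known biomass ratio.

The packaged ``mpe5_community.tsv`` fixture describes a pitfall-trap litter
community of 11 order/class-level taxa including seven Carabidae species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "ExpectedCommunity",
    "RatioReport",
    "load_expected_community",
    "detection_ratio",
    "biomass_correlation",
    "pair_ratio_report",
]


@dataclass(frozen=True)
class ExpectedCommunity:
    """Expected taxa: (name, rank, biomass_g); names unique within a rank."""

    taxa: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        for name, rank, biomass in self.taxa:
            if biomass <= 0:
                raise ValueError(f"{name!r}: biomass must be positive")
        for rank in self.ranks():
            names = [n for n, r, _ in self.taxa if r == rank]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate taxon names at rank {rank!r}")

    def ranks(self) -> list[str]:
        return sorted({r for _, r, _ in self.taxa})

    def at_rank(self, rank: str) -> dict[str, float]:
        return {n: b for n, r, b in self.taxa if r == rank}


@dataclass(frozen=True)
class RatioReport:
    numerator_taxon: str
    denominator_taxon: str
    ratio_5p: float
    ratio_3p: float

    @property
    def mean_ratio(self) -> float:
        return (self.ratio_5p + self.ratio_3p) / 2.0


def load_expected_community(path: str | Path | None = None) -> ExpectedCommunity:
    """Load a community TSV (name, rank, biomass); default: packaged fixture."""
    if path is None:
        source = resources.files("hsta.data").joinpath("mpe5_community.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    taxa = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, rank, biomass = line.split("\t")
        taxa.append((name, rank, float(biomass)))
    return ExpectedCommunity(taxa=tuple(taxa))


def _counts_at_rank(assigned: pd.DataFrame, rank: str) -> dict[str, float]:
    sub = assigned[assigned["rank"] == rank]
    return sub.groupby("taxon")["count"].sum().to_dict()


def detection_ratio(
    assigned: pd.DataFrame, expected: ExpectedCommunity, rank: str
) -> tuple[float, list[str], list[str]]:
    """Fraction of expected taxa with any assigned reads, plus found/missing lists."""
    exp = expected.at_rank(rank)
    if not exp:
        raise ValueError(f"no expected taxa at rank {rank!r}")
    counts = _counts_at_rank(assigned, rank)
    found = sorted(t for t in exp if counts.get(t, 0) > 0)
    missing = sorted(t for t in exp if counts.get(t, 0) <= 0)
    return len(found) / len(exp), found, missing


def biomass_correlation(
    assigned: pd.DataFrame, expected: ExpectedCommunity, rank: str
) -> float | None:
    """Pearson's r between read counts and biomass over detected expected taxa.

    Returns ``None`` (reported as missing) when fewer than two expected taxa
    were detected, where a correlation is undefined.
    """
    exp = expected.at_rank(rank)
    counts = _counts_at_rank(assigned, rank)
    pairs = [(counts[t], exp[t]) for t in exp if counts.get(t, 0) > 0]
    if len(pairs) < 2:
        return None
    xs, ys = zip(*pairs)
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return None  # zero variance: r undefined
    return float(pearsonr(xs, ys).statistic)


def pair_ratio_report(
    assigned: pd.DataFrame, taxon_a: str, taxon_b: str, rank: str = "species"
) -> RatioReport:
    """Per-strand read-count ratios taxon_a/taxon_b and their arithmetic mean.

    A zero denominator yields an infinite ratio (flagged by the caller via
    ``math.isinf``).
    """
    sub = assigned[assigned["rank"] == rank]
    ratios = {}
    for strand in ("5p", "3p"):
        s = sub[sub["strand"] == strand]
        num = float(s.loc[s["taxon"] == taxon_a, "count"].sum())
        den = float(s.loc[s["taxon"] == taxon_b, "count"].sum())
        ratios[strand] = num / den if den > 0 else math.inf
    return RatioReport(
        numerator_taxon=taxon_a,
        denominator_taxon=taxon_b,
        ratio_5p=ratios["5p"],
        ratio_3p=ratios["3p"],
    )
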