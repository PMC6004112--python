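"""GC-content / site-diversity diagnostic for sequencing bias.

If a sequencing chemistry makes more errors in GC-rich (or GC-poor)
stretches, the per-site diversity of reads will exceed what the biological
diversity of the references predicts, and the excess will track local GC
content.  The diagnostic regresses per-site read diversity on per-site
reference diversity and a windowed reference GC percentage,

    Dreads ~ Dref + GCref

where diversity is the exponential Shannon entropy of the base frequencies
at a column (the Hill number of order 1: the effective number of bases,
between 1 and 4), and GCref is the mean GC percentage of the references in
a 100-bp window around the site.  A sequential (Type I) ANOVA then
apportions the variance: a significant GCref term flags GC-dependent error
surviving the upstream denoising.

Two regions of the barcode are analyzed separately: the 5' region (first
400 alignment columns) and the 3' region (column 200 to the end), matching
the two strand-specific read sets such an amplicon run produces.
Coordinates are 1-based inclusive alignment columns.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DiversityProfile",
    "AnovaTable",
    "site_exp_entropy",
    "gc_track",
    "diversity_profiles",
    "slice_region",
    "fit_gc_model",
    "FIVE_PRIME_END",
    "THREE_PRIME_START",
]

logger = logging.getLogger(__name__)

FIVE_PRIME_END = 400  #: 5' region: columns 1..400
THREE_PRIME_START = 200  #: 3' region: columns 200..end
_BASES = "ACGT"


@dataclass(frozen=True)
class DiversityProfile:
    """Per-site covariates: read diversity, reference diversity, windowed GC%."""

    site_index: int  # 1-based alignment column
    d_reads: float
    d_ref: float
    gc_ref: float  # percent, 0..100


@dataclass
class AnovaTable:
    """Sequential variance decomposition of the diversity model.

    ``terms`` are (name, df, sum_sq) in fitting order; the residual row
    closes the decomposition.  F for each term is its mean square over the
    residual mean square; explained variance is its share of the total sum
    of squares.
    """

    terms: list[tuple[str, int, float]]
    residual_df: int
    residual_ss: float

    @property
    def total_ss(self) -> float:
        return sum(ss for _, _, ss in self.terms) + self.residual_ss

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def f_value(self, term: str) -> float:
        for name, df, ss in self.terms:
            if name == term:
                return (ss / df) / self.residual_ms
        raise KeyError(term)

    def p_value(self, term: str) -> float:
        from scipy.stats import f as f_dist

        for name, df, ss in self.terms:
            if name == term:
                return float(f_dist.sf(self.f_value(term), df, self.residual_df))
        raise KeyError(term)

    def explained_pct(self, term: str) -> float:
        if term == "Residuals":
            return 100.0 * self.residual_ss / self.total_ss
        for name, df, ss in self.terms:
            if name == term:
                return 100.0 * ss / self.total_ss
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, df, ss in self.terms:
            rows.append(
                {
                    "term": name,
                    "df": df,
                    "sum_sq": ss,
                    "mean_sq": ss / df,
                    "F": self.f_value(name),
                    "Pr(>F)": self.p_value(name),
                    "explained_pct": self.explained_pct(name),
                }
            )
        rows.append(
            {
                "term": "Residuals",
                "df": self.residual_df,
                "sum_sq": self.residual_ss,
                "mean_sq": self.residual_ms,
                "F": math.nan,
                "Pr(>F)": math.nan,
                "explained_pct": self.explained_pct("Residuals"),
            }
        )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(self.to_frame().to_dict(orient="records"))


def site_exp_entropy(column: Sequence[str]) -> float:
    """Hill number of order 1 for one alignment column.

    exp of the natural-log Shannon entropy of the A/C/G/T frequencies;
    1.0 for a monomorphic column, 4.0 for a uniform one.  Gaps and non-ACGT
    symbols are excluded; a column with no usable characters raises.
    """
    counts = np.array([sum(1 for c in column if c.upper() == b) for b in _BASES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("column has no A/C/G/T characters")
    p = counts[counts > 0] / total
    return float(np.exp(-np.sum(p * np.log(p))))


def gc_track(ref_rows: Sequence[str], window: int = 100) -> np.ndarray:
    """Windowed GC percentage per alignment column of the references.

    Per column, the G+C fraction among non-gap reference characters; then a
    centered moving average over ``window`` columns, truncated at the
    edges; scaled to percent.  Columns with no residues contribute NaN and
    are skipped by the moving average.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not ref_rows:
        raise ValueError("empty reference alignment")
    ncol = len(ref_rows[0])
    frac = np.full(ncol, np.nan)
    for c in range(ncol):
        chars = [r[c].upper() for r in ref_rows if r[c] != "-"]
        usable = [ch for ch in chars if ch in _BASES]
        if usable:
            frac[c] = sum(ch in "GC" for ch in usable) / len(usable)
    smooth = (
        pd.Series(frac).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )
    return smooth * 100.0


def diversity_profiles(
    read_rows: Sequence[str],
    ref_rows: Sequence[str],
    window: int = 100,
    min_reads: int = 1,
) -> list[DiversityProfile]:
    """Per-site diversity covariates from two alignments in shared coordinates.

    ``read_rows`` are assigned reads placed in the reference alignment's
    coordinate system (e.g. via ``hsta.profile_hmm.place_in_alignment``).
    Columns where either alignment has no usable characters, or with fewer
    than ``min_reads`` read residues, are excluded (logged).
    """
    if not read_rows or not ref_rows:
        raise ValueError("both alignments must be non-empty")
    ncol = len(ref_rows[0])
    if any(len(r) != ncol for r in ref_rows) or any(len(r) != ncol for r in read_rows):
        raise ValueError("reads and references must share one alignment length")
    gc = gc_track(ref_rows, window=window)
    out = []
    skipped = 0
    for c in range(ncol):
        read_col = [r[c] for r in read_rows if r[c] != "-" and r[c].upper() in _BASES]
        ref_col = [r[c] for r in ref_rows if r[c] != "-" and r[c].upper() in _BASES]
        if len(read_col) < min_reads or not ref_col or np.isnan(gc[c]):
            skipped += 1
            continue
        out.append(
            DiversityProfile(
                site_index=c + 1,
                d_reads=site_exp_entropy(read_col),
                d_ref=site_exp_entropy(ref_col),
                gc_ref=float(gc[c]),
            )
        )
    if skipped:
        logger.info("diversity_profiles: %d of %d columns excluded", skipped, ncol)
    return out


def slice_region(
    profile: Sequence[DiversityProfile], region: str
) -> list[DiversityProfile]:
    """Restrict to the 5' (columns 1..400) or 3' (columns 200..end) region."""
    sites = [p.site_index for p in profile]
    if any(a > b for a, b in zip(sites, sites[1:])):
        raise ValueError("profile must be sorted by site index")
    if region == "five_prime":
        last = sites[-1] if sites else 0
        if last < FIVE_PRIME_END:
            logger.warning(
                "alignment ends at column %d, before the nominal 5' bound %d; truncating",
                last,
                FIVE_PRIME_END,
            )
        return [p for p in profile if p.site_index <= FIVE_PRIME_END]
    if region == "three_prime":
        return [p for p in profile if p.site_index >= THREE_PRIME_START]
    raise ValueError(f"unknown region {region!r}; use 'five_prime' or 'three_prime'")


def fit_gc_model(
    rows: Sequence[DiversityProfile],
    term_order: tuple[str, str] = ("GCref", "Dref"),
):
    """OLS fit of Dreads on Dref and GCref with sequential (Type I) ANOVA.

    ``term_order`` controls the sequential decomposition; the default fits
    GCref first.  Sequential sums of squares depend on this order (the
    residual does not) — both orders are available rather than hidden.
    Returns ``(fitted_model, AnovaTable)``.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 complete sites to fit the model")
    name_map = {"GCref": "gc_ref", "Dref": "d_ref"}
    if set(term_order) != set(name_map):
        raise ValueError(f"term_order must be a permutation of {sorted(name_map)}")
    df = pd.DataFrame(
        {
            "d_reads": [r.d_reads for r in rows],
            "d_ref": [r.d_ref for r in rows],
            "gc_ref": [r.gc_ref for r in rows],
        }
    )
    for a, b in (("d_ref", "gc_ref"),):
        if df[a].nunique() == 1 or df[b].nunique() == 1:
            raise np.linalg.LinAlgError(
                f"constant covariate among ({a}, {b}): sequential ANOVA is singular"
            )
        if abs(np.corrcoef(df[a], df[b])[0, 1]) > 1.0 - 1e-12:
            raise np.linalg.LinAlgError(f"covariates {a} and {b} are collinear")
    formula = "d_reads ~ " + " + ".join(name_map[t] for t in term_order)
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=1)
    terms = []
    for t in term_order:
        row = table.loc[name_map[t]]
        terms.append((t, int(row["df"]), float(row["sum_sq"])))
    resid = table.loc["Residual"]
    return fit, AnovaTable(
        terms=terms,
        residual_df=int(resid["df"]),
        residual_ss=float(resid["sum_sq"]),
    )
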