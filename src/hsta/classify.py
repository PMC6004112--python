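"""Bayes-Factor hit discrimination and three-way assignment.

A query scanned against a collection of per-taxon profiles yields one bit
score per profile.  The decision rule is:

* **Unclassified** — the best hit's E-value exceeds the significance gate.
* **Good** — the best score stands out from its competitors: the log Bayes
  Factor

      ln(BF) = S_1 - ln( sum_{i>=2} exp(S_i) )

  exceeds the threshold (default 3.0).  The winning profile's taxon is
  reported.
* **Ambiguous** — significant, but the competitors are too close for the
  Bayes Factor to clear the threshold.

The Bayes Factor is applied to the bit scores exactly as written (natural
log of summed exponentiated bit scores); since bit scores are base-2
log-odds, a ``scale="nats"`` option converts them to natural-log units
first for the strictly Bayesian variant.  With a single significant hit the
sum is empty and ln(BF) is +infinity, so a lone hit is always Good.

The e-value gate default (10.0, the conventional hit-reporting default) and
the stricter inclusion-style preset (0.01) are both exposed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .profile_hmm import HitScore, ProfileHMM, scan
from .seqio import TaxonRecord

__all__ = [
    "BFResult",
    "Assignment",
    "ln_bayes_factor",
    "classify",
    "filter_hits_by_best_order",
    "assign_all",
    "EVALUE_GATE_REPORTING",
    "EVALUE_GATE_INCLUSION",
]

logger = logging.getLogger(__name__)

EVALUE_GATE_REPORTING = 10.0  #: conventional per-hit reporting threshold
EVALUE_GATE_INCLUSION = 0.01  #: stricter inclusion-style threshold

GOOD = "Good"
AMBIGUOUS = "Ambiguous"
UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class BFResult:
    query_id: str
    best_profile: str
    ln_bf: float  # +inf when n_hits == 1
    n_hits: int


@dataclass(frozen=True)
class Assignment:
    query_id: str
    category: str  # Good | Ambiguous | Unclassified
    rank: str
    taxon: str | None = None
    ln_bf: float | None = None
    best_bit_score: float | None = None
    best_evalue: float | None = None

    def __post_init__(self) -> None:
        if (self.category == GOOD) != (self.taxon is not None):
            raise ValueError("taxon must be present exactly when category is Good")


def ln_bayes_factor(scores: Sequence[float], scale: str = "bits") -> float:
    """Best score minus the log-sum-exp of the remaining scores.

    ``scores`` must be sorted descending.  ``scale="bits"`` applies the rule
    to the scores as given; ``scale="nats"`` multiplies by ln 2 first so the
    exponentials operate on natural-log odds.  Returns ``+inf`` for a single
    score (no competitors).
    """
    if len(scores) == 0:
        raise ValueError("ln_bayes_factor requires at least one score")
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise ValueError("scores must be sorted in descending order")
    if scale not in ("bits", "nats"):
        raise ValueError(f"unknown scale {scale!r}")
    s = np.asarray(scores, dtype=float)
    if scale == "nats":
        s = s * math.log(2.0)
    if len(s) == 1:
        return math.inf
    return float(s[0] - logsumexp(s[1:]))


def bf_result(hits: Sequence[HitScore], scale: str = "bits") -> BFResult:
    """Summarize one query's sorted hits as a Bayes-Factor record.

    ``ln_bf`` is infinite exactly when there is a single hit.
    """
    if not hits:
        raise ValueError("bf_result requires at least one hit")
    scores = [h.bit_score for h in hits]
    return BFResult(
        query_id=hits[0].query_id,
        best_profile=hits[0].profile_name,
        ln_bf=ln_bayes_factor(scores, scale=scale),
        n_hits=len(hits),
    )


def classify(
    hits: Sequence[HitScore],
    evalue_threshold: float = EVALUE_GATE_REPORTING,
    bf_threshold: float = 3.0,
    rank: str = "order",
    scale: str = "bits",
) -> Assignment:
    """Apply the three-category decision rule to one query's sorted hits.

    Only hits passing the e-value gate compete in the Bayes Factor: an
    insignificant far-off profile should not be able to demote an otherwise
    clear assignment to Ambiguous.
    """
    if not hits:
        logger.warning("query with no hits: Unclassified")
        return Assignment(query_id="", category=UNCLASSIFIED, rank=rank)
    if any(a.bit_score < b.bit_score for a, b in zip(hits, hits[1:])):
        raise ValueError("hits must be sorted by bit score descending")
    query_id = hits[0].query_id
    best = hits[0]
    if best.evalue > evalue_threshold:
        return Assignment(
            query_id=query_id,
            category=UNCLASSIFIED,
            rank=rank,
            best_bit_score=best.bit_score,
            best_evalue=best.evalue,
        )
    significant = [h.bit_score for h in hits if h.evalue <= evalue_threshold]
    ln_bf = ln_bayes_factor(significant, scale=scale)
    if ln_bf > bf_threshold:
        return Assignment(
            query_id=query_id,
            category=GOOD,
            rank=rank,
            taxon=best.profile_name,
            ln_bf=ln_bf,
            best_bit_score=best.bit_score,
            best_evalue=best.evalue,
        )
    return Assignment(
        query_id=query_id,
        category=AMBIGUOUS,
        rank=rank,
        ln_bf=ln_bf,
        best_bit_score=best.bit_score,
        best_evalue=best.evalue,
    )


def filter_hits_by_best_order(table: pd.DataFrame) -> pd.DataFrame:
    """Keep, per query, only hits sharing the best hit's taxonomic order.

    ``table`` has columns ``query_id, subject_id, subject_order_label,
    bit_score, rank_position`` (rank_position 1 = best).  Rows lacking an
    order label are dropped with a warning; if the *best* hit lacks one, the
    whole query is dropped with a warning.
    """
    required = {"query_id", "subject_id", "subject_order_label", "bit_score", "rank_position"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    out = []
    for query_id, group in table.groupby("query_id", sort=False):
        group = group.sort_values("rank_position")
        best = group.iloc[0]
        if best["rank_position"] != 1:
            raise ValueError(f"query {query_id!r} has no rank_position-1 row")
        best_order = best["subject_order_label"]
        if not isinstance(best_order, str) or not best_order:
            logger.warning("query %r: best hit has no order label; query dropped", query_id)
            continue
        labeled = group["subject_order_label"].astype("string").fillna("") != ""
        if (~labeled).any():
            logger.warning(
                "query %r: %d unlabeled hit rows dropped", query_id, int((~labeled).sum())
            )
        out.append(group[labeled & (group["subject_order_label"] == best_order)])
    if not out:
        return table.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def assign_all(
    queries: Iterable[TaxonRecord],
    profiles: Sequence[ProfileHMM],
    evalue_threshold: float = EVALUE_GATE_REPORTING,
    bf_threshold: float = 3.0,
    rank: str = "order",
    scale: str = "bits",
    sample: str = "sample",
    strand: str = "5p",
) -> tuple[list[Assignment], pd.DataFrame]:
    """Scan and classify every query against one rank's profile collection.

    Returns the per-query assignments and an abundance table (DataFrame with
    columns ``taxon, rank, sample, strand, count``) counting Good
    assignments per taxon.
    """
    assignments = []
    counts: dict[str, int] = {}
    for q in queries:
        hits = scan(q, profiles)
        a = classify(
            hits,
            evalue_threshold=evalue_threshold,
            bf_threshold=bf_threshold,
            rank=rank,
            scale=scale,
        )
        assignments.append(a)
        if a.category == GOOD:
            counts[a.taxon] = counts.get(a.taxon, 0) + 1
    abundance = pd.DataFrame(
        [
            {"taxon": t, "rank": rank, "sample": sample, "strand": strand, "count": c}
            for t, c in sorted(counts.items())
        ],
        columns=["taxon", "rank", "sample", "strand", "count"],
    )
    return assignments, abundance


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Tabulate assignments for TSV output."""
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "rank": a.rank,
                "category": a.category,
                "taxon": a.taxon if a.taxon is not None else "",
                "ln_bf": a.ln_bf if a.ln_bf is not None else "",
                "best_bit_score": a.best_bit_score if a.best_bit_score is not None else "",
                "best_evalue": a.best_evalue if a.best_evalue is not None else "",
            }
            for a in assignments
        ]
    )
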