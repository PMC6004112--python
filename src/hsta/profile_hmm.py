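"""Per-taxon nucleotide profile HMMs with local forward scoring.

The model is a Plan-7-style profile over {A,C,G,T}: match states with
position-specific emissions, insert states emitting background, delete
states, and *exactly uniform* local fragment entry/exit — entering match
state k (0-based) with probability 2(M-k)/(M(M+1)) and exiting from match
state k with probability 1/(M-k) makes every match fragment [k, l] equally
likely a priori.  Unannotated flanking residues are emitted by background
loop states whose self-loop probability equals the geometric null model's
(tau = L/(L+1)), so flank emissions cancel in the odds ratio.

Scores are reported in bits:

    S = log2( P(seq | profile, local) / P(seq | background) )

computed by the forward algorithm (full path sum) in log space.  There is
no filter pipeline and no heuristic: with tens of per-taxon profiles rather
than Pfam-scale libraries, exact forward is affordable.

Significance is calibrated per profile by fitting a Gumbel (EVD) to forward
scores of shuffled consensus sequences; E-values are n_targets times the
Gumbel survival function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .backalign import CodonAlignment
from .seqio import TaxonRecord

__all__ = [
    "ProfileHMM",
    "HitScore",
    "EvalueCalibration",
    "build_profile",
    "forward_bits",
    "align_to_profile",
    "viterbi_bits",
    "place_in_alignment",
    "calibrate_evalue",
    "evalue",
    "scan",
    "save_profiles",
    "load_profiles",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_LN2 = float(np.log(2.0))
_NEG = -np.inf


@dataclass
class EvalueCalibration:
    profile_name: str
    gumbel_mu: float
    gumbel_lambda: float
    n_shuffles: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.gumbel_lambda > 0 and np.isfinite(self.gumbel_lambda)):
            raise ValueError(
                f"degenerate Gumbel fit for {self.profile_name!r}: lambda={self.gumbel_lambda}"
            )


@dataclass(frozen=True)
class HitScore:
    query_id: str
    profile_name: str
    bit_score: float
    evalue: float


@dataclass
class ProfileHMM:
    """A calibratable nucleotide profile HMM.

    Emissions are stored as probabilities; transition arrays are indexed by
    the 0-based source state.  Local alignments begin and end on match
    states, so the last delete state is structurally unreachable: ``t_md``
    into it and ``t_dd`` out of its predecessor are zero.
    """

    name: str
    rank: str
    M: int
    match_emissions: np.ndarray  # (M, 4) probabilities
    insert_emissions: np.ndarray  # (max(M-1,1), 4) probabilities
    t_mm: np.ndarray  # (M-1,) source M_k -> M_{k+1}
    t_mi: np.ndarray  # M_k -> I_k
    t_md: np.ndarray  # M_k -> D_{k+1}
    t_im: np.ndarray  # I_k -> M_{k+1}
    t_ii: np.ndarray  # I_k -> I_k
    t_dm: np.ndarray  # D_k -> M_{k+1}
    t_dd: np.ndarray  # D_k -> D_{k+1}
    background: np.ndarray  # (4,)
    match_columns: tuple[int, ...] = ()  # 1-based source-alignment columns
    calibration: EvalueCalibration | None = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("profile must have at least one match state")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    # -- derived quantities -------------------------------------------------

    @property
    def entry(self) -> np.ndarray:
        """P(begin -> M_k): uniform-fragment entry, heavier toward the 5' end."""
        k = np.arange(self.M)
        return 2.0 * (self.M - k) / (self.M * (self.M + 1))

    @property
    def p_exit(self) -> np.ndarray:
        """P(M_k -> end); 1/(M-k) makes the exit point uniform given entry."""
        k = np.arange(self.M)
        return 1.0 / (self.M - k)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.match_emissions, axis=1))

    def state_distributions(self) -> dict[str, np.ndarray]:
        """Per-state outgoing probability totals (each must be 1)."""
        if self.M == 1:
            return {"match": self.p_exit.copy()}
        stay = 1.0 - self.p_exit[:-1]
        out = {
            "match": np.concatenate(
                [
                    self.p_exit[:-1] + stay * (self.t_mm + self.t_mi + self.t_md),
                    [self.p_exit[-1]],
                ]
            ),
            "insert": self.t_im + self.t_ii,
        }
        if self.M > 2:
            # delete states run D_1 .. D_{M-2} (0-based)
            out["delete"] = (self.t_dm + self.t_dd)[1 : self.M - 1]
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "format": "hsta-profile-v1",
            "name": self.name,
            "rank": self.rank,
            "M": self.M,
            "background": self.background.tolist(),
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {
                t: getattr(self, f"t_{t}").tolist()
                for t in ("mm", "mi", "md", "im", "ii", "dm", "dd")
            },
            "match_columns": list(self.match_columns),
        }
        if self.calibration is not None:
            d["calibration"] = asdict(self.calibration)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        if d.get("format") != "hsta-profile-v1":
            raise ValueError(f"unrecognized profile format {d.get('format')!r}")
        calib = d.get("calibration")
        return cls(
            name=d["name"],
            rank=d["rank"],
            M=d["M"],
            match_emissions=np.asarray(d["match_emissions"], dtype=float),
            insert_emissions=np.asarray(d["insert_emissions"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            match_columns=tuple(d.get("match_columns", ())),
            calibration=EvalueCalibration(**calib) if calib else None,
            **{
                f"t_{t}": np.asarray(d["transitions"][t], dtype=float)
                for t in ("mm", "mi", "md", "im", "ii", "dm", "dd")
            },
        )


def save_profiles(profiles: Iterable[ProfileHMM], path: str | Path) -> None:
    """Write a profile collection as JSON lines."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(json.dumps(p.to_dict()) + "\n")


def load_profiles(path: str | Path) -> list[ProfileHMM]:
    with open(path) as fh:
        return [ProfileHMM.from_dict(json.loads(line)) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Building


def _rows_of(aln) -> list[str]:
    if isinstance(aln, CodonAlignment) or hasattr(aln, "rows"):
        return list(aln.rows)
    return [str(r).upper() for r in aln]


def build_profile(
    aln,
    name: str,
    rank: str = "order",
    occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
    transition_pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a gapped nucleotide alignment.

    Match columns are those whose gap fraction is strictly below
    ``occupancy_threshold`` (a column at exactly the threshold is an insert
    column).  Emissions use Laplace-style pseudocounts:
    ``(count + pseudocount) / (total + 4 * pseudocount)``; ``N`` residues are
    excluded from the counts.  Transitions are counted from each row's
    match/insert/delete path, with ``transition_pseudocount`` added to every
    structurally allowed transition (it must be positive so every allowed
    transition stays reachable).
    """
    rows = _rows_of(aln)
    if len(rows) < 2:
        raise ValueError("profile building requires at least 2 aligned sequences")
    if transition_pseudocount <= 0:
        raise ValueError("transition_pseudocount must be positive")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows must have equal length")
    allowed = set("ACGTN-")
    for r in rows:
        bad = set(r) - allowed
        if bad:
            raise ValueError(f"unexpected alignment characters {sorted(bad)}")

    nrow = len(rows)
    is_match = [
        sum(r[c] == "-" for r in rows) / nrow < occupancy_threshold
        for c in range(ncol)
    ]
    match_cols = [c for c in range(ncol) if is_match[c]]
    M = len(match_cols)
    if M == 0:
        raise ValueError("alignment has no match columns (all columns too gappy)")

    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must sum to 1")

    counts = np.zeros((M, 4))
    for k, c in enumerate(match_cols):
        for r in rows:
            ch = r[c]
            if ch in _BASE_INDEX:
                counts[k, _BASE_INDEX[ch]] += 1
    match_em = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
    )

    nT = max(M - 1, 0)
    c_tr = {t: np.zeros(nT) for t in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    col_to_k = {c: k for k, c in enumerate(match_cols)}
    for r in rows:
        # state path between the first and last match columns; flanking
        # insert columns belong to the N/C flanks and are skipped
        path: list[tuple[str, int]] = []
        k_passed = 0
        for c in range(ncol):
            if is_match[c]:
                k = col_to_k[c]
                path.append(("M" if r[c] != "-" else "D", k))
                k_passed = k + 1
            elif r[c] != "-" and 0 < k_passed < M:
                path.append(("I", k_passed - 1))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "D" and k1 == 0:
                continue  # D_0 is unreachable in the model
            key = (s1 + s2).lower()
            if key in c_tr:
                idx = k1 - 1 if s1 == "D" else k1
                c_tr[key][idx] += 1
            # I<->D adjacencies are not Plan-7 transitions; skipped

    tp = transition_pseudocount
    # forbid entry into / continuation through the unreachable last delete
    if nT:
        c_tr["md"][-1] = 0.0
        c_tr["dd"][-1] = 0.0

    def _norm(keys: list[str], masks: list[np.ndarray]) -> list[np.ndarray]:
        padded = [c_tr[key] + tp * m for key, m in zip(keys, masks)]
        total = sum(padded)
        total = np.where(total > 0, total, 1.0)
        return [p / total for p in padded]

    if nT:
        ones = np.ones(nT)
        md_mask = ones.copy()
        md_mask[-1] = 0.0
        dd_mask = md_mask.copy()
        t_mm, t_mi, t_md = _norm(["mm", "mi", "md"], [ones, ones, md_mask])
        t_im, t_ii = _norm(["im", "ii"], [ones, ones])
        t_dm, t_dd = _norm(["dm", "dd"], [ones, dd_mask])
    else:
        t_mm = t_mi = t_md = t_im = t_ii = t_dm = t_dd = np.zeros(0)

    return ProfileHMM(
        name=name,
        rank=rank,
        M=M,
        match_emissions=match_em,
        insert_emissions=np.tile(bg, (max(nT, 1), 1)),
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        background=bg,
        match_columns=tuple(c + 1 for c in match_cols),
    )


# ---------------------------------------------------------------------------
# Scoring


def _encode(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("cannot score an empty sequence")
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(raw), 4, dtype=np.int64)  # 4 = background symbol (N etc.)
    for b, i in _BASE_INDEX.items():
        out[raw == ord(b)] = i
    return out


def _log_params(profile: ProfileHMM):
    """Natural-log emission odds and effective transition probabilities."""
    with np.errstate(divide="ignore"):
        bg = profile.background
        lo_m = np.log(profile.match_emissions / bg)
        lo_m = np.concatenate([lo_m, np.zeros((profile.M, 1))], axis=1)  # col 4: N
        lo_i = np.log(profile.insert_emissions / bg)
        lo_i = np.concatenate([lo_i, np.zeros((lo_i.shape[0], 1))], axis=1)
        stay = 1.0 - profile.p_exit[:-1] if profile.M > 1 else np.zeros(0)
        a = {
            "entry": np.log(profile.entry),
            "exit": np.log(profile.p_exit),
            "mm": np.log(stay * profile.t_mm),
            "mi": np.log(stay * profile.t_mi),
            "md": np.log(stay * profile.t_md),
            "im": np.log(profile.t_im),
            "ii": np.log(profile.t_ii),
            "dm": np.log(profile.t_dm),
            "dd": np.log(profile.t_dd),
        }
    return lo_m, lo_i, a


def _lse(v: np.ndarray) -> float:
    m = np.max(v)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(v - m))))


def _delete_chain(
    vM_new: np.ndarray, a_md: np.ndarray, a_dd: np.ndarray, M: int, op=np.logaddexp
) -> np.ndarray:
    """Values of D_1..D_{M-2} at a fixed sequence position.

    vD[j] = op(vM[j-1] + md[j-1], vD[j-1] + dd[j-1]); solved in one pass via
    a prefix accumulate with the dd chain factored out.  ``op`` is
    ``np.logaddexp`` for forward and ``np.maximum`` for Viterbi.
    """
    vD = np.full(M, _NEG)
    if M <= 2:
        return vD
    # T[j] = sum of dd log-probs along D_1 -> D_j (T for j=1..M-2)
    dd_inner = a_dd[1 : M - 2]  # D_1->D_2 .. D_{M-3}->D_{M-2}
    if dd_inner.size and not np.all(np.isfinite(dd_inner)):
        # zero-probability dd links: fall back to the direct recurrence
        for j in range(1, M - 1):
            frm = vM_new[j - 1] + a_md[j - 1]
            fdd = vD[j - 1] + a_dd[j - 1] if j > 1 else _NEG
            vD[j] = op(frm, fdd)
        return vD
    T = np.concatenate([[0.0], np.cumsum(dd_inner)])  # aligned with D_1..D_{M-2}
    c = vM_new[: M - 2] + a_md[: M - 2] - T
    acc = op.accumulate(c)
    vD[1 : M - 1] = T + acc
    return vD


def forward_bits(profile: ProfileHMM, seq: str) -> float:
    """Local forward log-odds score of ``seq`` against ``profile``, in bits."""
    x = _encode(seq)
    L = len(x)
    M = profile.M
    lo_m, lo_i, a = _log_params(profile)
    tau = L / (L + 1.0)
    ln_tau = np.log(tau)

    vM = np.full(M, _NEG)
    vI = np.full(max(M - 1, 1), _NEG)
    vD = np.full(M, _NEG)
    ends = np.full(L, _NEG)

    for i in range(L):
        em_m = lo_m[:, x[i]] - ln_tau
        if M > 1:
            em_i = lo_i[:, x[i]] - ln_tau
            vI_new = em_i + np.logaddexp(vM[:-1] + a["mi"], vI + a["ii"])
        else:
            vI_new = vI
        from_prev = np.full(M, _NEG)
        if M > 1:
            from_prev[1:] = np.logaddexp(
                np.logaddexp(vM[:-1] + a["mm"], vI + a["im"]),
                vD[:-1] + a["dm"],
            )
        vM_new = em_m + np.logaddexp(a["entry"], from_prev)
        vD_new = _delete_chain(vM_new, a["md"], a["dd"], M) if M > 2 else np.full(M, _NEG)
        vM, vI, vD = vM_new, vI_new, vD_new
        ends[i] = _lse(vM + a["exit"])
    total = _lse(ends)
    return float((np.log(1.0 - tau) + total) / _LN2)


def _viterbi_fill(profile: ProfileHMM, seq: str):
    x = _encode(seq)
    L = len(x)
    M = profile.M
    lo_m, lo_i, a = _log_params(profile)
    tau = L / (L + 1.0)
    ln_tau = np.log(tau)

    vM = np.full((L, M), _NEG)
    vI = np.full((L, max(M - 1, 1)), _NEG)
    vD = np.full((L, M), _NEG)

    for i in range(L):
        em_m = lo_m[:, x[i]] - ln_tau
        if M > 1 and i > 0:
            em_i = lo_i[:, x[i]] - ln_tau
            vI[i] = em_i + np.maximum(vM[i - 1, :-1] + a["mi"], vI[i - 1] + a["ii"])
        from_prev = np.full(M, _NEG)
        if M > 1 and i > 0:
            from_prev[1:] = np.maximum(
                np.maximum(vM[i - 1, :-1] + a["mm"], vI[i - 1] + a["im"]),
                vD[i - 1, :-1] + a["dm"],
            )
        vM[i] = em_m + np.maximum(a["entry"], from_prev)
        if M > 2:
            vD[i] = _delete_chain(vM[i], a["md"], a["dd"], M, op=np.maximum)
    return x, vM, vI, vD, a, lo_m, tau


def viterbi_bits(profile: ProfileHMM, seq: str) -> float:
    """Best single local alignment path score in bits.

    Unlike :func:`forward_bits` (which sums all paths and therefore gains
    mass logarithmically from background flanks), the max-path score is
    stable under flanking: the best path is unchanged and only the length
    model shifts, by well under a bit for moderate flanks.
    """
    x, vM, vI, vD, a, lo_m, tau = _viterbi_fill(profile, seq)
    best = float(np.max(vM + a["exit"]))
    return float((np.log(1.0 - tau) + best) / _LN2)


def align_to_profile(profile: ProfileHMM, seq: str) -> str:
    """Viterbi-align ``seq`` to the profile's match-state coordinates.

    Returns a string of length ``M``: the query residue assigned to each
    match state, ``-`` where the best path deletes or never visits the
    state.  Insert-state residues and flanking residues are dropped.  This
    places an assigned read into the coordinate system of the reference
    alignment the profile was built from (see :func:`place_in_alignment`).
    """
    x, vM, vI, vD, a, lo_m, tau = _viterbi_fill(profile, seq)
    end_scores = vM + a["exit"]
    i, k = map(int, np.unravel_index(np.argmax(end_scores), end_scores.shape))
    out = ["-"] * profile.M
    state = "M"
    while True:
        if state == "M":
            out[k] = _BASES[x[i]] if x[i] < 4 else "N"
            if i == 0 or k == 0:
                break  # only local entry can precede
            options = [
                (a["entry"][k], "B"),
                (vM[i - 1, k - 1] + a["mm"][k - 1], "M"),
                (vI[i - 1, k - 1] + a["im"][k - 1], "I"),
                (vD[i - 1, k - 1] + a["dm"][k - 1], "D"),
            ]
            best_val, best_state = max(options, key=lambda t: t[0])
            if best_state == "B":
                break
            i, k, state = i - 1, k - 1, best_state
        elif state == "I":
            # in I_k at row i (an insert residue; not placed in the output)
            if vM[i - 1, k] + a["mi"][k] >= vI[i - 1, k] + a["ii"][k]:
                state = "M"
            i -= 1
        else:  # state == "D", in D_k at row i
            frm = vM[i, k - 1] + a["md"][k - 1]
            fdd = vD[i, k - 1] + a["dd"][k - 1] if k > 1 else _NEG
            if frm >= fdd:
                k, state = k - 1, "M"
            else:
                k, state = k - 1, "D"
    return "".join(out)


def place_in_alignment(profile: ProfileHMM, seq: str, alignment_length: int) -> str:
    """Expand :func:`align_to_profile` output to source-alignment coordinates."""
    if not profile.match_columns:
        raise ValueError("profile has no recorded source match columns")
    aligned = align_to_profile(profile, seq)
    out = ["-"] * alignment_length
    for ch, col in zip(aligned, profile.match_columns):
        out[col - 1] = ch
    return "".join(out)


# ---------------------------------------------------------------------------
# Calibration and scanning


def calibrate_evalue(
    profile: ProfileHMM, n_shuffles: int = 200, seed: int = 0
) -> EvalueCalibration:
    """Fit a Gumbel null distribution to scores of shuffled consensus sequences."""
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable Gumbel fit")
    rng = np.random.default_rng(seed)
    consensus = np.array(list(profile.consensus()))
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        scores[i] = forward_bits(profile, "".join(rng.permutation(consensus)))
    loc, scale = gumbel_r.fit(scores)
    return EvalueCalibration(
        profile_name=profile.name,
        gumbel_mu=float(loc),
        gumbel_lambda=float(1.0 / scale),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def evalue(calibration: EvalueCalibration, bit_score: float, n_targets: int = 1) -> float:
    """Expected number of hits at or above ``bit_score`` among ``n_targets``.

    The Gumbel survival function is evaluated as ``-expm1(-exp(-lambda(s-mu)))``
    to stay strictly positive and monotone deep into the tail, where the
    textbook ``1 - cdf`` underflows to zero.
    """
    z = calibration.gumbel_lambda * (bit_score - calibration.gumbel_mu)
    return float(n_targets * -np.expm1(-np.exp(-z)))


def scan(query: TaxonRecord, profiles: Sequence[ProfileHMM]) -> list[HitScore]:
    """Score a query against every profile; sorted by bit score desc, ties by name."""
    if not profiles:
        raise ValueError("scan requires at least one profile")
    hits = []
    for p in profiles:
        if p.calibration is None:
            raise ValueError(f"profile {p.name!r} is not calibrated; run calibrate_evalue first")
        s = forward_bits(p, query.seq)
        hits.append(
            HitScore(
                query_id=query.id,
                profile_name=p.name,
                bit_score=s,
                evalue=evalue(p.calibration, s, n_targets=len(profiles)),
            )
        )
    hits.sort(key=lambda h: (-h.bit_score, h.profile_name))
    return hits
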