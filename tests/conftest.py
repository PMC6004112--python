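"""Shared fixtures: tiny profiles, a small simulated community, and the
brute-force path-enumeration oracle for local forward scores."""

from __future__ import annotations

import numpy as np
import pytest

from hsta import (
    CommunitySpec,
    ErrorModel,
    TaxonSpec,
    build_profile,
    calibrate_evalue,
    evolve_references,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_bits(profile, seq: str) -> float:
    """Independent forward oracle: exhaustive enumeration of every local
    alignment path, in plain probability space.

    Mirrors the generative story directly: uniform-fragment local entry and
    exit, background-emitting flanks with loop probability tau = L/(L+1)
    cancelling against the geometric null, core emissions contributing
    their odds ratio and a 1/tau factor each.  Only feasible for tiny
    profiles and queries.
    """
    M = profile.M
    L = len(seq)
    x = [_BASE_INDEX.get(c.upper(), 4) for c in seq]
    bg = profile.background
    tau = L / (L + 1.0)
    stay = 1.0 - profile.p_exit

    def em_ratio(k: int, pos: int) -> float:
        return float(profile.match_emissions[k][x[pos]] / bg[x[pos]]) if x[pos] < 4 else 1.0

    def ins_ratio(k: int, pos: int) -> float:
        return float(profile.insert_emissions[k][x[pos]] / bg[x[pos]]) if x[pos] < 4 else 1.0

    def from_match(k: int, pos: int) -> list[float]:
        """Total odds of paths entering M_k with x[pos] and eventually exiting."""
        if pos >= L:
            return []
        r0 = em_ratio(k, pos) / tau
        out = [r0 * profile.p_exit[k]]
        if k < M - 1:
            for r in from_match(k + 1, pos + 1):
                out.append(r0 * stay[k] * profile.t_mm[k] * r)
            for r in from_insert(k, pos + 1):
                out.append(r0 * stay[k] * profile.t_mi[k] * r)
            if k + 1 <= M - 2:
                for r in from_delete(k + 1, pos + 1):
                    out.append(r0 * stay[k] * profile.t_md[k] * r)
        return out

    def from_insert(k: int, pos: int) -> list[float]:
        if pos >= L:
            return []
        r0 = ins_ratio(k, pos) / tau
        out = []
        for r in from_match(k + 1, pos + 1):
            out.append(r0 * profile.t_im[k] * r)
        for r in from_insert(k, pos + 1):
            out.append(r0 * profile.t_ii[k] * r)
        return out

    def from_delete(j: int, pos: int) -> list[float]:
        out = []
        for r in from_match(j + 1, pos):
            out.append(profile.t_dm[j] * r)
        if j + 1 <= M - 2:
            for r in from_delete(j + 1, pos):
                out.append(profile.t_dd[j] * r)
        return out

    total = 0.0
    for s in range(L):
        for k in range(M):
            total += profile.entry[k] * sum(from_match(k, s))
    return float(np.log2((1.0 - tau) * total))


@pytest.fixture(scope="session")
def small_spec() -> CommunitySpec:
    """Three orders, seven species, short references: the workhorse community."""
    return CommunitySpec(
        taxa=(
            TaxonSpec("OrdA", n_species=3, biomass_g=22.89),
            TaxonSpec("OrdB", n_species=2, biomass_g=4.12),
            TaxonSpec("OrdC", n_species=2, biomass_g=1.02),
        ),
        ancestor_length_codons=150,
        error_model=ErrorModel(
            base_sub_rate=0.004, gc_sub_slope=0.01, homopolymer_indel_rate=0.01,
            read_length=250,
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_refs(small_spec):
    return evolve_references(small_spec)


def profiles_from_refs(refs, rank: str, n_shuffles: int = 100, seed: int = 5):
    """Group ungapped same-length references by label and build calibrated profiles."""
    groups: dict[str, list[str]] = {}
    for r in refs:
        label = r.order_label if rank == "order" else r.species_label
        groups.setdefault(label, []).append(r.seq)
    profiles = []
    for name in sorted(groups):
        p = build_profile(groups[name], name=name, rank=rank)
        p.calibration = calibrate_evalue(p, n_shuffles=n_shuffles, seed=seed)
        profiles.append(p)
    return profiles


@pytest.fixture(scope="session")
def order_profiles(small_refs):
    return profiles_from_refs(small_refs, "order")


@pytest.fixture(scope="session")
def species_profiles(small_refs):
    return profiles_from_refs(small_refs, "species")
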