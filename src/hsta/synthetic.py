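"""Mock-community generator for end-to-end validation.

The generator emulates the statistical structure of a pyrosequenced
invertebrate pitfall-trap community: order- and species-structured
coxI-like coding references, biomass-weighted read sampling with per-taxon
amplification-bias multipliers, and 454-style read errors with a
GC-dependent substitution component and homopolymer indels.

References evolve on star trees — a random stop-free ancestor, one star of
order ancestors, one star of species per order, and a shallow star of
individuals per species — with codon-position-weighted substitution (third
positions evolve 4x faster than first, first 2x faster than second,
mirroring the constraint pattern of a protein-coding mitochondrial gene).
Star trees are deliberately simple: they control the divergence tiers
directly without pretending to be a realistic phylogeny.

Defaults describe the emulated study conditions: a 657-nt (219-codon)
Folmer-length coxI fragment, ~30% expected substitutions/site between
orders, ~5% between congeneric species, ~0.5% between conspecific
individuals, three sequenced individuals per species, 250-nt reads with a
0.4% baseline substitution rate plus a GC-dependent excess, and a 1%
per-homopolymer indel rate.  The biomass-equalized vs. natural-biomass
sample designs are a single boolean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .backalign import GENETIC_CODES, DEFAULT_CODE
from .seqio import TaxonRecord
from Bio.Data import CodonTable

__all__ = [
    "ErrorModel",
    "TaxonSpec",
    "CommunitySpec",
    "default_community",
    "evolve_references",
    "sample_reads",
]

_BASES = "ACGT"
#: relative substitution weights by codon position (1st, 2nd, 3rd)
_CODON_POS_WEIGHT = np.array([2.0, 1.0, 8.0])


@dataclass(frozen=True)
class ErrorModel:
    """454-style read-error model.

    ``base_sub_rate`` is the per-base substitution probability at 0% GC;
    ``gc_sub_slope`` adds to it in proportion to the GC fraction of the
    100-bp reference window around the base, embodying GC-dependent
    sequencing error.  ``homopolymer_indel_rate`` is the probability that a
    homopolymer run of length >= 3 gains or loses one base, the signature
    454 failure mode.
    """

    base_sub_rate: float = 0.004
    gc_sub_slope: float = 0.01
    homopolymer_indel_rate: float = 0.01
    read_length: int = 250
    gc_window: int = 100

    def __post_init__(self) -> None:
        for name in ("base_sub_rate", "gc_sub_slope", "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not (0 <= v < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")


@dataclass(frozen=True)
class TaxonSpec:
    order_label: str
    n_species: int
    biomass_g: float
    bias_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.biomass_g <= 0 or self.bias_multiplier <= 0:
            raise ValueError(f"{self.order_label}: biomass and bias must be positive")
        if self.n_species < 1:
            raise ValueError(f"{self.order_label}: need at least one species")


@dataclass(frozen=True)
class CommunitySpec:
    taxa: tuple[TaxonSpec, ...]
    ancestor_length_codons: int = 219
    order_divergence: float = 0.30
    species_divergence: float = 0.05
    individual_divergence: float = 0.005
    individuals_per_species: int = 3
    error_model: ErrorModel = field(default_factory=ErrorModel)
    genetic_code: str = DEFAULT_CODE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("order_divergence", "species_divergence", "individual_divergence"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.ancestor_length_codons < 20:
            raise ValueError("ancestor must be at least 20 codons")

    def echo_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def default_community(seed: int = 0, error_model: ErrorModel | None = None) -> CommunitySpec:
    """The emulated study community: 11 order/class taxa, 7 carabid species.

    Biomasses follow the measured litter community (grams); only the beetle
    group is resolved to species.
    """
    taxa = (
        TaxonSpec("Coleoptera", n_species=7, biomass_g=22.89),
        TaxonSpec("Diptera", 1, 4.12),
        TaxonSpec("Orthoptera", 1, 2.44),
        TaxonSpec("Blattodea", 1, 1.02),
        TaxonSpec("Myriapoda", 1, 0.82),
        TaxonSpec("Isopoda", 1, 0.7),
        TaxonSpec("Arachnida", 1, 0.64),
        TaxonSpec("Scorpiones", 1, 0.63),
        TaxonSpec("Hymenoptera", 1, 0.21),
        TaxonSpec("Lepidoptera", 1, 0.1),
        TaxonSpec("Collembola", 1, 0.02),
    )
    return CommunitySpec(
        taxa=taxa, seed=seed, error_model=error_model or ErrorModel()
    )


def _stop_codons(code: str) -> set[str]:
    return set(CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code]].stop_codons)


def _random_ancestor(rng: np.random.Generator, n_codons: int, stops: set[str]) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)


def _mutate(
    rng: np.random.Generator, seq: str, divergence: float, stops: set[str]
) -> str:
    """Substitute bases at expected ``divergence`` subs/site, stop-free.

    Per-site rates are codon-position weighted (normalized so the mean rate
    equals ``divergence``); a codon mutated into a stop is re-drawn.
    """
    if divergence == 0:
        return seq
    n = len(seq)
    weights = np.tile(_CODON_POS_WEIGHT / _CODON_POS_WEIGHT.mean(), n // 3)
    rates = np.minimum(divergence * weights, 0.95)
    out = list(seq)
    for codon_start in range(0, n - n % 3, 3):
        for _attempt in range(50):
            codon = list(seq[codon_start : codon_start + 3])
            hit = rng.random(3) < rates[codon_start : codon_start + 3]
            for p in np.nonzero(hit)[0]:
                current = codon[p]
                codon[p] = rng.choice([b for b in _BASES if b != current])
            if "".join(codon) not in stops:
                out[codon_start : codon_start + 3] = codon
                break
        # after 50 failed draws the codon is left ancestral (vanishingly rare)
    return "".join(out)


def evolve_references(spec: CommunitySpec) -> list[TaxonRecord]:
    """Simulate the reference set: individuals nested in species in orders.

    Record ids are ``{order}_sp{j}_ind{k}``; species labels are
    ``{order}_sp{j}``.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    stops = _stop_codons(spec.genetic_code)
    ancestor = _random_ancestor(rng, spec.ancestor_length_codons, stops)
    records = []
    for taxon in spec.taxa:
        order_seq = _mutate(rng, ancestor, spec.order_divergence, stops)
        for j in range(1, taxon.n_species + 1):
            species_seq = _mutate(rng, order_seq, spec.species_divergence, stops)
            species_label = f"{taxon.order_label}_sp{j}"
            for k in range(1, spec.individuals_per_species + 1):
                ind_seq = _mutate(rng, species_seq, spec.individual_divergence, stops)
                records.append(
                    TaxonRecord(
                        id=f"{species_label}_ind{k}",
                        seq=ind_seq,
                        order_label=taxon.order_label,
                        species_label=species_label,
                    )
                )
    return records


def _gc_fraction_windows(seq: str, window: int) -> np.ndarray:
    """GC fraction of the centered ``window`` around each position."""
    is_gc = np.array([c in "GC" for c in seq], dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(is_gc, kernel, mode="same")
    counts = np.convolve(np.ones_like(is_gc), kernel, mode="same")
    return sums / counts


def _apply_errors(
    rng: np.random.Generator, fragment: str, gc_window_frac: np.ndarray, model: ErrorModel
) -> str:
    rates = np.minimum(model.base_sub_rate + model.gc_sub_slope * gc_window_frac, 0.75)
    bases = list(fragment)
    hit = rng.random(len(bases)) < rates
    for p in np.nonzero(hit)[0]:
        bases[p] = rng.choice([b for b in _BASES if b != bases[p]])
    if model.homopolymer_indel_rate > 0:
        out = []
        i = 0
        while i < len(bases):
            j = i
            while j < len(bases) and bases[j] == bases[i]:
                j += 1
            run = bases[i:j]
            if j - i >= 3 and rng.random() < model.homopolymer_indel_rate:
                if rng.random() < 0.5:
                    run = run + [bases[i]]  # one base over-called
                else:
                    run = run[:-1]  # one base under-called
            out.extend(run)
            i = j
        bases = out
    return "".join(bases)


def sample_reads(
    refs: list[TaxonRecord],
    spec: CommunitySpec,
    n_reads: int,
    equalize_biomass: bool = False,
    seed: int | None = None,
) -> tuple[list[TaxonRecord], list[dict]]:
    """Draw error-bearing reads from the references.

    Per-taxon read counts are multinomial with weights
    ``biomass x bias_multiplier`` (bias only when ``equalize_biomass``,
    emulating the ad-hoc equal-biomass sample); within a taxon, species and
    individuals are uniform.  Each read is a uniform-start fragment of
    ``read_length`` (the whole reference if shorter) with substitutions at
    ``base_sub_rate + gc_sub_slope x window-GC`` and homopolymer indels.

    Returns ``(reads, truth)`` where ``truth`` rows record the source
    order/species/reference and fragment start (1-based) per read id.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if n_reads == 0:
        return [], []
    by_order: dict[str, list[TaxonRecord]] = {}
    for r in refs:
        by_order.setdefault(r.order_label, []).append(r)
    weights = []
    orders = []
    for taxon in spec.taxa:
        if taxon.order_label not in by_order:
            raise ValueError(f"no references for taxon {taxon.order_label!r}")
        w = taxon.bias_multiplier * (1.0 if equalize_biomass else taxon.biomass_g)
        weights.append(w)
        orders.append(taxon.order_label)
    weights = np.asarray(weights) / np.sum(weights)
    counts = rng.multinomial(n_reads, weights)
    model = spec.error_model
    gc_cache = {r.id: _gc_fraction_windows(r.seq, model.gc_window) for r in refs}
    reads = []
    truth = []
    read_no = 0
    for order_label, count in zip(orders, counts):
        members = by_order[order_label]
        picks = rng.integers(0, len(members), size=count)
        for pick in picks:
            ref = members[pick]
            read_no += 1
            if len(ref.seq) <= model.read_length:
                start = 0
                fragment = ref.seq
            else:
                start = int(rng.integers(0, len(ref.seq) - model.read_length + 1))
                fragment = ref.seq[start : start + model.read_length]
            gc_frac = gc_cache[ref.id][start : start + len(fragment)]
            read_seq = _apply_errors(rng, fragment, gc_frac, model)
            read_id = f"read_{read_no:06d}"
            reads.append(
                TaxonRecord(
                    id=read_id,
                    seq=read_seq,
                    order_label=ref.order_label,
                    species_label=ref.species_label,
                )
            )
            truth.append(
                {
                    "read_id": read_id,
                    "order_label": ref.order_label,
                    "species_label": ref.species_label or "",
                    "ref_id": ref.id,
                    "start": start + 1,
                }
            )
    return reads, truth
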