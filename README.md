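# hsta — profile-HMM taxonomic assignment for coxI metabarcoding

`hsta` (Hidden States Taxa Assign) assigns amplicon reads from mixed
invertebrate samples to taxa **without an OTU clustering step**.  Reference
coxI barcode sequences are grouped per taxon (order rank, and species rank
where available), back-aligned codon-by-codon through a protein alignment,
and turned into nucleotide profile HMMs.  Each denoised read is scored
against every profile with a local forward algorithm; the winning taxon is
accepted only when it beats the field decisively.

It is aimed at people running DNA metabarcoding experiments on mock or
environmental communities who want a classifier whose decisions are
probabilistic scores rather than similarity cutoffs, together with the
diagnostics that usually accompany such an experiment: a GC-bias regression
on per-site diversity, detection/biomass statistics against a known
community, and a read simulator to validate the whole pipeline.

## The decision rule

A read scored against profiles `1..n` yields bit scores `S_1 >= S_2 >= ...`
(log2 odds of profile vs. background, forward path sum).  Writing

    ln(BF) = S_1 - ln( sum_{i=2..n} exp(S_i) )

the read is

* **Unclassified** if the best hit's E-value (per-profile Gumbel
  calibration on shuffled sequences) exceeds the significance gate;
* **Good**, assigned to the best profile's taxon, if `ln(BF) > 3.0`;
* **Ambiguous** otherwise — significant, but competitors are too close.

A companion linear model diagnoses GC-dependent sequencing error that
survived denoising: per alignment column,

    Dreads ~ Dref + GCref

where `D` is the exponential Shannon entropy of the base frequencies (the
Hill number of order 1, an effective number of bases between 1 and 4) and
`GCref` the mean reference GC% in a 100-bp window.  A sequential (Type I)
ANOVA apportions the variance; a significant `GCref` term (conditioned on
`Dref`) means read diversity tracks GC content beyond what biology
explains.

## A worked example

```python
from hsta import (CommunitySpec, TaxonSpec, evolve_references, sample_reads,
                  build_profile, calibrate_evalue)
from hsta.classify import assign_all

spec = CommunitySpec(
    taxa=(TaxonSpec("Coleoptera", n_species=3, biomass_g=22.89),
          TaxonSpec("Diptera", n_species=1, biomass_g=4.12),
          TaxonSpec("Orthoptera", n_species=1, biomass_g=2.44)),
    ancestor_length_codons=120, seed=2)
refs = evolve_references(spec)
reads, truth = sample_reads(refs, spec, n_reads=60)

profiles = []
for order in ("Coleoptera", "Diptera", "Orthoptera"):
    p = build_profile([r.seq for r in refs if r.order_label == order],
                      name=order, rank="order")
    p.calibration = calibrate_evalue(p, n_shuffles=100, seed=1)
    profiles.append(p)

assignments, abundance = assign_all(reads, profiles, rank="order")
```

This prints (see `examples/03_classify_reads.py`):

```
built 3 calibrated profiles (M = 360 match states)
60/60 reads Good, 60 correctly labeled

abundance table (Good assignments per taxon):
     taxon  rank sample strand  count
Coleoptera order sample     5p     49
   Diptera order sample     5p      8
Orthoptera order sample     5p      3

example: read_000001 -> Coleoptera, ln(BF) = 273.7 (best bit score 284.3, E = 9.2e-258)
```

Every read is accepted (`ln(BF)` far above 3: on clean data the true
taxon's profile dwarfs its competitors) and the per-taxon counts track the
biomass weighting of the simulator (49:8:3 against 22.89:4.12:2.44 g).
The `examples/` directory has one short script per capability —
simulation, back-alignment, classification, the GC diagnostic, and
community evaluation — each printing the numbers it computes and what
they mean.

A thin CLI mirrors the library:
`hsta simulate | backalign | build | scan | classify | gcmodel | evaluate`,
each writing a JSON manifest of every seed and threshold used.

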