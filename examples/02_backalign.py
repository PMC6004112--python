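"""Protein-guided back-alignment of coding references.

Nucleotide references are translated (invertebrate mitochondrial code),
aligned at the protein level, and the codons are threaded back through the
protein alignment.  Gaps therefore always appear as whole codons and the
nucleotide columns respect the reading frame — the alignment a codon-aware
profile HMM should be built from.
"""

from hsta import TaxonRecord, align_proteins, back_align, translate

# three short coxI-like fragments; the second carries a one-codon deletion
records = [
    TaxonRecord("ref1", "ATAATTGGAGGATTTGGAAATTGA", "Coleoptera"),
    TaxonRecord("ref2", "ATAATTGGATTTGGAAATTGA", "Coleoptera"),
    TaxonRecord("ref3", "ATAATCGGAGGATTCGGTAATTGA", "Coleoptera"),
]
proteins = [translate(r.seq, frame=0) for r in records]
print("translations:", proteins)

msa = align_proteins([r.id for r in records], proteins)
for rec_id, row in zip(msa.ids, msa.rows):
    print(f"  {rec_id}  {row}")

codon_aln = back_align(records, msa, frame=0)
print("\nback-aligned nucleotides (gaps come in whole codons):")
for rec_id, row in zip(codon_aln.ids, codon_aln.rows):
    print(f"  {rec_id}  {row}")

assert all(codon_aln.ungapped(r.id) == r.seq for r in records)
print("\nungapping each row reproduces the input sequence exactly.")
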