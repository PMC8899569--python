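"""Canonical Kcnq4 p.W276S amplicon fixture.

The 101-nt sequence below is the published single-stranded DNA donor used to
create the Kcnq4 c.830G>C (p.W276S) knock-in mouse.  It carries the mutant
allele: the pathogenic c.830G>C base (Trp TGG -> Ser TCG codon) and, 20 nt
upstream, the phased synonymous marker c.810C>A that tags mutant-allele reads
in allele-specific indel analysis.

On the wild-type sequence derived from this donor, the knock-in sgRNA
protospacer CCTCCTATGCCGACTCGCTC occupies offsets 37-56 with PAM TGG at 57-59
and the SpCas9 blunt cut falls between offsets 53 and 54 (3 bp 5' of the PAM).
"""

from __future__ import annotations

from .reference import AlleleSite, AmpliconReference

KCNQ4_W276S_DONOR = (
    "TCTACCTGGCTGAGAAGGATGCCAACTCTGACTTCTCCTC"
    "ATATGCCGACTCGCTCTGGTCGGGGACGGTGCGTGAGCAT"
    "CTGTGCAGGGCTGCCCTTACC"
)

MARKER_OFFSET = 41       # c.810C>A  (WT C, mutant A)
PATHOGENIC_OFFSET = 61   # c.830G>C  (WT G, mutant C; TGG Trp -> TCG Ser)

KNOCKIN_PROTOSPACER = "CCTCCTATGCCGACTCGCTC"
KNOCKIN_PAM = "TGG"
KNOCKIN_SPAN = (37, 56)
KNOCKIN_CUT_OFFSET = 53  # blunt cut between offsets 53 and 54


def kcnq4_w276s_amplicon() -> AmpliconReference:
    """The mutant-allele donor amplicon with marker and pathogenic sites."""
    return AmpliconReference(
        id="Kcnq4-W276S-donor",
        sequence=KCNQ4_W276S_DONOR,
        sites=(
            AlleleSite(offset=MARKER_OFFSET, wt_base="C", mut_base="A",
                       role="marker"),
            AlleleSite(offset=PATHOGENIC_OFFSET, wt_base="G", mut_base="C",
                       role="pathogenic"),
        ),
    )
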