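"""SpCas9 guide (sgRNA) enumeration and annotation on amplicon references.

Every 5'-NGG-3' protospacer-adjacent motif whose 20-nt protospacer window fits
on the amplicon yields one :class:`GuideCandidate`.  Both strands are scanned;
candidates can be restricted to those whose protospacer covers the pathogenic
variant, the property that makes a guide allele-selective for a dominant
variant (one mismatch against the wild-type allele).

Coordinates are 1-based inclusive on the top strand.  SpCas9 cuts bluntly
3 bp 5' of the PAM, i.e. between protospacer positions 17 and 18; cut sites
are between-base positions reported as the offset of the base on the 5' (left,
top-strand) side of the cut.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .reference import AmpliconReference, allele_sequence

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_FROM_PAM = 3  # blunt cut 3 nt 5' of the PAM


@dataclass(frozen=True)
class GuideCandidate:
    """One protospacer/PAM occurrence on the reference.

    ``start``/``end`` delimit the protospacer on the top strand (1-based,
    inclusive) regardless of strand; ``protospacer`` and ``pam`` read 5'->3'
    on the guide's own strand.  ``variant_pos_in_protospacer`` counts 1-20
    from the protospacer's 5' end; ``pam_distance_of_variant`` counts from the
    PAM-proximal end (position 20 -> distance 1).
    """

    protospacer: str
    pam: str
    strand: str
    start: int
    end: int
    cut_offset: int
    variant_pos_in_protospacer: int | None = None
    pam_distance_of_variant: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")
        if not (self.start <= self.cut_offset < self.end):
            raise ValueError("cut site must fall strictly inside the protospacer span")


def cut_site(guide: GuideCandidate) -> int:
    """Between-base cut position (offset of the base 5' of the cut, top strand).

    Recomputed from strand and span so it is stable under re-annotation:
    on '+' the cut falls between protospacer positions 17|18 (start+16|start+17
    on the reference); on '-' the mirrored position is start+2|start+3.
    """
    if guide.strand == "+":
        return guide.end - CUT_FROM_PAM
    return guide.start + CUT_FROM_PAM - 1


def _variant_annotation(start: int, end: int, strand: str,
                        variant_offset: int | None) -> tuple[int | None, int | None]:
    if variant_offset is None or not (start <= variant_offset <= end):
        return None, None
    if strand == "+":
        pos = variant_offset - start + 1
    else:
        pos = end - variant_offset + 1
    return pos, PROTOSPACER_LEN - pos + 1


def enumerate_guides(ref: AmpliconReference, allele: str = "mutant",
                     require_variant_overlap: bool = False,
                     strands: str = "both") -> list[GuideCandidate]:
    """Enumerate every NGG guide candidate on the chosen allele sequence.

    Parameters
    ----------
    allele
        ``"mutant"`` scans the stored sequence, ``"wt"`` the derived wild-type.
    require_variant_overlap
        Keep only candidates whose protospacer covers the pathogenic site.
    strands
        ``"top"``, ``"bottom"`` or ``"both"``.

    Candidates are returned sorted by top-strand span start (then strand),
    so output is deterministic.
    """
    if strands not in ("top", "bottom", "both"):
        raise ValueError(f"unknown strand selection {strands!r}")
    seq = allele_sequence(ref, allele)
    n = len(seq)
    path = ref.pathogenic_site
    variant_offset = path.offset if path else None
    if require_variant_overlap and variant_offset is None:
        raise ValueError("require_variant_overlap needs a pathogenic site annotation")

    out: list[GuideCandidate] = []
    if strands in ("top", "both"):
        # PAM N-G-G at 0-based i..i+2 with a full 20-nt window upstream
        for i in range(PROTOSPACER_LEN, n - 2):
            if seq[i + 1] == "G" and seq[i + 2] == "G":
                start = i - PROTOSPACER_LEN + 1  # 1-based
                end = i                          # 1-based inclusive
                pos, dist = _variant_annotation(start, end, "+", variant_offset)
                out.append(GuideCandidate(
                    protospacer=seq[i - PROTOSPACER_LEN:i],
                    pam=seq[i:i + 3],
                    strand="+", start=start, end=end,
                    cut_offset=end - CUT_FROM_PAM,
                    variant_pos_in_protospacer=pos,
                    pam_distance_of_variant=dist,
                ))
    if strands in ("bottom", "both"):
        # NGG on the bottom strand appears as CCN on the top strand
        for j in range(0, n - PROTOSPACER_LEN - 2):
            if seq[j] == "C" and seq[j + 1] == "C":
                start = j + 4                    # 1-based protospacer span
                end = j + 3 + PROTOSPACER_LEN
                pos, dist = _variant_annotation(start, end, "-", variant_offset)
                out.append(GuideCandidate(
                    protospacer=reverse_complement(seq[j + 3:j + 3 + PROTOSPACER_LEN]),
                    pam=reverse_complement(seq[j:j + 3]),
                    strand="-", start=start, end=end,
                    cut_offset=start + CUT_FROM_PAM - 1,
                    variant_pos_in_protospacer=pos,
                    pam_distance_of_variant=dist,
                ))
    if require_variant_overlap:
        out = [g for g in out if g.start <= variant_offset <= g.end]
    out.sort(key=lambda g: (g.start, g.strand))
    return out


@dataclass(frozen=True)
class AlleleDiscriminationReport:
    overlaps_pathogenic: bool
    pam_distance_of_variant: int | None
    wt_protospacer: str


def allele_discrimination(guide: GuideCandidate,
                          ref: AmpliconReference) -> AlleleDiscriminationReport:
    """How a guide reads on the wild-type allele.

    A guide whose protospacer covers the pathogenic site sees a one-base
    mismatch on the wild-type allele (``wt_protospacer`` differs from
    ``protospacer``), the basis of allele-selective cutting.
    """
    path = ref.pathogenic_site
    if path is None:
        raise ValueError("reference has no pathogenic site annotation")
    wt = allele_sequence(ref, "wt")
    segment = wt[guide.start - 1:guide.end]
    wt_protospacer = segment if guide.strand == "+" else reverse_complement(segment)
    overlaps = guide.start <= path.offset <= guide.end
    _, dist = _variant_annotation(guide.start, guide.end, guide.strand, path.offset)
    return AlleleDiscriminationReport(
        overlaps_pathogenic=overlaps,
        pam_distance_of_variant=dist,
        wt_protospacer=wt_protospacer,
    )
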