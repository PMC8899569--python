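"""Allele-specific indel quantification of amplicon sequencing reads.

The classification rule: a read is assigned to the mutant allele only if it
carries the phased synonymous marker base; among mutant-allele reads, only
those with a net out-of-frame indel of 1-8 bp at the Cas9 cut site count as
edited.  In-frame indels and indels longer than 8 bp are tallied separately
(``mutant_excluded``) — they are compatible with sequencing/PCR artifacts or
non-disruptive repair and never enter the edited numerator.  Editing efficacy
is the edited fraction of all mutant-marker reads, in percent.

Background correction subtracts the apparent efficacy of a non-injected
control sample (contralateral ear or uninjected animal) from the injected
sample, flooring at zero, to remove sequencing-noise baseline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignedRead, AlignmentParams, align_read
from .guides import GuideCandidate, cut_site
from .reference import AmpliconReference

READ_CLASSES = ("mutant_edited", "mutant_unedited", "mutant_excluded",
                "wt", "discarded")

#: (ref_offset, signed length, inserted sequence) of one window indel
WindowIndel = tuple[int, int, str]


@dataclass(frozen=True)
class QuantConfig:
    """Parameters of the allele-specific quantification.

    ``window_halfwidth`` bounds the reference interval around the cut site in
    which indels are attributed to the nuclease.  Indels whose net length L
    satisfies ``min_out_of_frame_len <= |L| <= max_indel_len`` and
    ``L % 3 != 0`` count as editing.  ``denominator`` chooses the efficacy
    denominator: ``"mutant"`` (all mutant-marker reads, the default) or
    ``"all"`` (all classified reads).
    """

    window_halfwidth: int = 5
    min_out_of_frame_len: int = 1
    max_indel_len: int = 8
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    denominator: str = "mutant"

    def __post_init__(self) -> None:
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")
        if not (1 <= self.min_out_of_frame_len <= self.max_indel_len):
            raise ValueError("require 1 <= min_out_of_frame_len <= max_indel_len")
        if self.denominator not in ("mutant", "all"):
            raise ValueError("denominator must be 'mutant' or 'all'")


def call_marker(ar: AlignedRead, ref: AmpliconReference) -> str | None:
    """Read the allele marker column from an aligned read.

    Returns ``"mutant"``, ``"wt"``, ``"other"`` (mismatching base or deleted
    column), or ``None`` when the alignment does not cover the marker offset
    (such reads are discarded, not counted).
    """
    site = ref.marker_site
    if site is None:
        raise ValueError("reference has no marker site annotation")
    off = site.offset
    if not ar.covers(off):
        return None
    for op in ar.ops:
        if op.op == "I":
            continue
        if op.ref_offset <= off < op.ref_offset + op.length:
            if op.op == "D":
                return "other"
            base = (site.mut_base if op.op == "M"
                    else op.read_seq[off - op.ref_offset])
            if base == site.mut_base:
                return "mutant"
            if base == site.wt_base:
                return "wt"
            return "other"
    return None


def call_indels(ar: AlignedRead, cut_offset: int,
                cfg: QuantConfig | None = None) -> list[WindowIndel]:
    """Indel operations whose reference footprint intersects the cut window.

    The window is ``[cut_offset - w, cut_offset + w]`` (1-based, inclusive)
    with ``w = cfg.window_halfwidth``.  A deletion occupies
    ``[ref_offset, ref_offset + len - 1]``; an insertion sits at the
    between-base position ``ref_offset``.  Substitutions are never indels.
    """
    cfg = cfg or QuantConfig()
    lo = cut_offset - cfg.window_halfwidth
    hi = cut_offset + cfg.window_halfwidth
    out: list[WindowIndel] = []
    for op in ar.ops:
        if op.op == "D":
            if op.ref_offset <= hi and op.ref_offset + op.length - 1 >= lo:
                out.append((op.ref_offset, -op.length, ""))
        elif op.op == "I":
            if lo <= op.ref_offset <= hi:
                out.append((op.ref_offset, op.length, op.read_seq))
    return out


def classify_read(marker_call: str | None,
                  indels_in_window: Sequence[WindowIndel],
                  cfg: QuantConfig | None = None,
                  aligned_ok: bool = True) -> str:
    """Assign one of the five read classes.

    Net indel length L is the sum of signed window-indel lengths; multiple
    indels are summed before the frame test.  Mutant-marker reads with
    ``1 <= |L| <= max_indel_len`` and ``L % 3 != 0`` are edited; mutant reads
    with indels that fail the test (in-frame net length, |L| beyond the cap,
    or net zero) are excluded; mutant reads without window indels are
    unedited.  Wild-type-marker reads are ``wt`` whatever their indels;
    uncovered/failed alignments and non-allelic marker bases are discarded.
    """
    cfg = cfg or QuantConfig()
    if not aligned_ok or marker_call is None or marker_call == "other":
        return "discarded"
    if marker_call == "wt":
        return "wt"
    if marker_call != "mutant":
        raise ValueError(f"unknown marker call {marker_call!r}")
    if not indels_in_window:
        return "mutant_unedited"
    net = sum(length for _, length, _ in indels_in_window)
    if (net != 0 and cfg.min_out_of_frame_len <= abs(net) <= cfg.max_indel_len
            and net % 3 != 0):
        return "mutant_edited"
    return "mutant_excluded"


@dataclass
class SampleQuantResult:
    """Per-sample quantification report."""

    counts: dict[str, int]
    total_reads: int
    marker_positive: int
    efficacy_percent: float | None
    efficacy_defined: bool
    indel_spectrum: dict[int, int]
    cut_offset: int
    window: tuple[int, int]
    config: QuantConfig

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total_reads": self.total_reads,
            "marker_positive": self.marker_positive,
            "efficacy_percent": self.efficacy_percent,
            "efficacy_defined": self.efficacy_defined,
            "indel_spectrum": {str(k): v for k, v in
                               sorted(self.indel_spectrum.items())},
            "cut_offset": self.cut_offset,
            "window": list(self.window),
            "window_halfwidth": self.config.window_halfwidth,
            "max_indel_len": self.config.max_indel_len,
            "denominator": self.config.denominator,
        }


def _resolve_cut(guide_or_cut: GuideCandidate | int) -> int:
    if isinstance(guide_or_cut, GuideCandidate):
        return cut_site(guide_or_cut)
    return int(guide_or_cut)


def classify_sample(reads: Iterable[tuple[str, str]], ref: AmpliconReference,
                    guide_or_cut: GuideCandidate | int,
                    cfg: QuantConfig | None = None):
    """Yield ``(read_id, read_class, AlignedRead)`` for every read.

    ``reads`` iterates ``(read_id, sequence)`` pairs; qualities are not used
    (no quality filtering by default).
    """
    cfg = cfg or QuantConfig()
    cut = _resolve_cut(guide_or_cut)
    lo, hi = cut - cfg.window_halfwidth, cut + cfg.window_halfwidth
    for read_id, seq in reads:
        ar = align_read(seq, ref, cfg.alignment, read_id=read_id)
        if ar.discarded or not (ar.covers(ref.marker_site.offset)
                                and ar.ref_start <= lo and ar.ref_end >= hi):
            ar.marker_call = None
            yield read_id, "discarded", ar
            continue
        ar.marker_call = call_marker(ar, ref)
        ar.indels_in_window = call_indels(ar, cut, cfg)
        yield read_id, classify_read(ar.marker_call, ar.indels_in_window, cfg), ar


def quantify_sample(reads: Iterable[tuple[str, str]], ref: AmpliconReference,
                    guide_or_cut: GuideCandidate | int,
                    cfg: QuantConfig | None = None) -> SampleQuantResult:
    """Align, call and classify every read; report counts and efficacy.

    Efficacy (%) = 100 x mutant_edited / denominator, where the default
    denominator is all mutant-marker reads (edited + unedited + excluded).
    With zero denominator reads the efficacy is undefined (``None``) and
    flagged, never silently 0.
    """
    cfg = cfg or QuantConfig()
    cut = _resolve_cut(guide_or_cut)
    counts = Counter({c: 0 for c in READ_CLASSES})
    spectrum: Counter[int] = Counter()
    total = 0
    for _, cls, ar in classify_sample(reads, ref, guide_or_cut, cfg):
        total += 1
        counts[cls] += 1
        if cls in ("mutant_edited", "mutant_excluded") and ar.indels_in_window:
            spectrum[sum(l for _, l, _ in ar.indels_in_window)] += 1
    if total == 0:
        raise ValueError("empty read set")
    marker_positive = (counts["mutant_edited"] + counts["mutant_unedited"]
                       + counts["mutant_excluded"])
    denom = (marker_positive if cfg.denominator == "mutant"
             else total - counts["discarded"])
    defined = denom > 0
    efficacy = 100.0 * counts["mutant_edited"] / denom if defined else None
    return SampleQuantResult(
        counts=dict(counts), total_reads=total,
        marker_positive=marker_positive,
        efficacy_percent=efficacy, efficacy_defined=defined,
        indel_spectrum=dict(spectrum),
        cut_offset=cut,
        window=(cut - cfg.window_halfwidth, cut + cfg.window_halfwidth),
        config=cfg,
    )


@dataclass(frozen=True)
class CorrectedEfficacy:
    corrected_percent: float
    injected_percent: float
    control_percent: float
    floored: bool


def background_correct(injected: SampleQuantResult,
                       control: SampleQuantResult) -> CorrectedEfficacy:
    """Injected-minus-control efficacy, floored at zero.

    Both samples must have been quantified with the same cut site and
    configuration; both raw values are retained in the report, and a control
    exceeding the injected sample floors to 0 with ``floored=True``.
    """
    same = (injected.cut_offset == control.cut_offset
            and injected.config == control.config)
    if not same:
        raise ValueError("injected and control were quantified with different "
                         "reference/guide/config; cannot compare")
    if not (injected.efficacy_defined and control.efficacy_defined):
        raise ValueError("efficacy undefined in one of the samples")
    diff = injected.efficacy_percent - control.efficacy_percent
    return CorrectedEfficacy(
        corrected_percent=max(0.0, diff),
        injected_percent=injected.efficacy_percent,
        control_percent=control.efficacy_percent,
        floored=diff < 0,
    )
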