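"""Two-allele amplicon references with annotated marker / pathogenic sites.

An :class:`AmpliconReference` stores the *mutant*-allele amplicon sequence —
the therapeutic target in allele-selective editing — together with the single-
base sites that distinguish it from the wild-type allele.  The wild-type
sequence is always derived on demand, never stored, so the two can never
drift apart.

Coordinates are 1-based and inclusive on the top strand throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
SITE_ROLES = ("marker", "pathogenic")


class ReferenceIntegrityError(ValueError):
    """An annotated site disagrees with the stored sequence."""


@dataclass(frozen=True)
class AlleleSite:
    """A single-base difference between the mutant and wild-type alleles.

    Parameters
    ----------
    offset
        1-based position on the amplicon top strand.
    wt_base, mut_base
        The wild-type and mutant-allele bases at that position.
    role
        ``"marker"`` for the phased synonymous tag that identifies
        mutant-allele reads, ``"pathogenic"`` for the disease variant.
    """

    offset: int
    wt_base: str
    mut_base: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in SITE_ROLES:
            raise ValueError(f"unknown site role {self.role!r}")
        if self.offset < 1:
            raise ValueError("site offset must be a positive 1-based position")
        for b in (self.wt_base, self.mut_base):
            if b not in VALID_BASES:
                raise ValueError(f"site base {b!r} not one of A/C/G/T")
        if self.wt_base == self.mut_base:
            raise ValueError("wt_base and mut_base must differ")


@dataclass(frozen=True)
class AmpliconReference:
    """Mutant-allele amplicon with its allele-distinguishing sites.

    ``sequence`` is the mutant allele; the canonical use case carries exactly
    one marker and one pathogenic site, but any number (including zero) is
    accepted so long as every site's ``mut_base`` matches the sequence.
    """

    id: str
    sequence: str
    sites: tuple[AlleleSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "sites", tuple(self.sites))
        if not seq:
            raise ValueError("empty amplicon sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence contains unsupported characters {sorted(bad)}; "
                "amplicon references must be fully resolved (no N/IUPAC codes)"
            )
        seen_offsets = set()
        for site in self.sites:
            if site.offset > len(seq):
                raise ReferenceIntegrityError(
                    f"site offset {site.offset} beyond sequence length {len(seq)}"
                )
            if seq[site.offset - 1] != site.mut_base:
                raise ReferenceIntegrityError(
                    f"sequence has {seq[site.offset - 1]!r} at offset "
                    f"{site.offset}, expected mutant base {site.mut_base!r}"
                )
            if site.offset in seen_offsets:
                raise ReferenceIntegrityError(
                    f"duplicate site annotation at offset {site.offset}"
                )
            seen_offsets.add(site.offset)

    def _site(self, role: str) -> AlleleSite | None:
        hits = [s for s in self.sites if s.role == role]
        if len(hits) > 1:
            raise ReferenceIntegrityError(f"multiple {role} sites annotated")
        return hits[0] if hits else None

    @property
    def marker_site(self) -> AlleleSite | None:
        return self._site("marker")

    @property
    def pathogenic_site(self) -> AlleleSite | None:
        return self._site("pathogenic")

    def base_at(self, offset: int) -> str:
        return self.sequence[offset - 1]


def derive_wt_sequence(ref: AmpliconReference) -> str:
    """Wild-type amplicon sequence: the mutant sequence with each annotated
    site's ``wt_base`` substituted in place. Length is unchanged."""
    seq = list(ref.sequence)
    for site in ref.sites:
        seq[site.offset - 1] = site.wt_base
    return "".join(seq)


def apply_sites(wt_sequence: str, sites: Iterable[AlleleSite]) -> str:
    """Inverse of :func:`derive_wt_sequence`: re-introduce the mutant bases."""
    seq = list(wt_sequence.upper())
    for site in sites:
        if seq[site.offset - 1] != site.wt_base:
            raise ReferenceIntegrityError(
                f"wild-type sequence has {seq[site.offset - 1]!r} at offset "
                f"{site.offset}, expected {site.wt_base!r}"
            )
        seq[site.offset - 1] = site.mut_base
    return "".join(seq)


def allele_sequence(ref: AmpliconReference, allele: str) -> str:
    """Return the requested allele's sequence (``"mutant"`` or ``"wt"``)."""
    if allele == "mutant":
        return ref.sequence
    if allele == "wt":
        if not ref.sites:
            raise ReferenceIntegrityError(
                "no allele sites annotated; wild-type sequence is not derivable"
            )
        return derive_wt_sequence(ref)
    raise ValueError(f"unknown allele {allele!r}")


# ---------------------------------------------------------------------------
# IO: FASTA reference + JSON/YAML site sidecar
# ---------------------------------------------------------------------------

def _sites_from_records(records: Sequence[dict]) -> tuple[AlleleSite, ...]:
    return tuple(
        AlleleSite(
            offset=int(r["offset"]),
            wt_base=str(r["wt_base"]).upper(),
            mut_base=str(r["mut_base"]).upper(),
            role=str(r["role"]),
        )
        for r in records
    )


def load_reference(fasta_path: str | Path, sites_path: str | Path | None = None,
                   sites: Sequence[dict] | None = None) -> AmpliconReference:
    """Load an amplicon reference from FASTA plus a JSON/YAML site sidecar.

    The sidecar holds a list of ``{offset, wt_base, mut_base, role}`` records;
    alternatively the same records may be passed inline via ``sites``.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    site_records: Sequence[dict] = sites or ()
    if sites_path is not None:
        text = Path(sites_path).read_text()
        loaded = (json.loads(text) if str(sites_path).endswith(".json")
                  else yaml.safe_load(text))
        site_records = loaded["sites"] if isinstance(loaded, dict) else loaded
    return AmpliconReference(
        id=record.id,
        sequence=str(record.seq).upper(),
        sites=_sites_from_records(site_records),
    )


def write_reference(ref: AmpliconReference, fasta_path: str | Path,
                    sites_path: str | Path | None = None) -> None:
    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.id, description="")],
                str(fasta_path), "fasta")
    if sites_path is not None:
        payload = {
            "sites": [
                {"offset": s.offset, "wt_base": s.wt_base,
                 "mut_base": s.mut_base, "role": s.role}
                for s in ref.sites
            ]
        }
        Path(sites_path).write_text(yaml.safe_dump(payload, sort_keys=False))
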