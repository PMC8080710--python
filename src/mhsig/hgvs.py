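"""Parsers for the HGVS deletion and truncation notations used in
myeloid-malignancy cohort tables.

Only the forms needed for deletion-signature work are supported:
coding deletions (``c.1092_1143del52``, ``c.100del``), protein nonsense
changes (``p.R693*``) and protein frameshifts (``p.E635fs*15``).
"""

from __future__ import annotations

import re

from .types import CdsDeletion, ProteinTruncation


class HgvsParseError(ValueError):
    pass


_CDS_DEL = re.compile(
    r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?del(?P<len>\d+)?$"
)

_AA3 = "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val|Ter"
_PROT = re.compile(
    rf"^p\.(?:\(?)(?P<aa>[A-Z]|{_AA3})(?P<pos>\d+)"
    r"(?:(?P<star>\*|Ter)|(?P<fs>fs)(?:\*|Ter)(?P<stop>\d+))\)?$"
)


def parse_cds_deletion(text: str) -> CdsDeletion:
    """Parse an HGVS coding-deletion name like ``c.284_307del24``.

    The deleted length is ``end - start + 1``; if the name carries an
    explicit length suffix it must agree with the coordinate span.
    """
    m = _CDS_DEL.match(text.strip())
    if m is None:
        raise HgvsParseError(f"not a coding deletion: {text!r}")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    if end < start:
        raise HgvsParseError(f"end precedes start in {text!r}")
    span = end - start + 1
    if m.group("len") is not None and int(m.group("len")) != span:
        raise HgvsParseError(
            f"declared length {m.group('len')} != coordinate span {span} in {text!r}"
        )
    return CdsDeletion(start, end)


def format_cds_deletion(d: CdsDeletion, with_length: bool = True) -> str:
    """Inverse of :func:`parse_cds_deletion` (round-trips)."""
    if d.cds_start == d.cds_end:
        return f"c.{d.cds_start}del"
    suffix = str(d.length) if with_length else ""
    return f"c.{d.cds_start}_{d.cds_end}del{suffix}"


def parse_protein_truncation(
    text: str, fs_convention: str = "stop_included"
) -> ProteinTruncation:
    """Parse a truncating HGVS p. name (``p.R693*`` or ``p.G646fs*12``).

    For a nonsense change at residue ``pos`` the last intact residue is
    ``pos - 1``.  For a frameshift ``fs*N`` the default convention takes
    the changed residue as codon 1 of the shifted frame and codon N as
    the stop, so ``last_intact_aa = pos + N - 2``; set
    ``fs_convention="stop_excluded"`` for the alternative reading
    (``pos + N - 1``) in which N counts readthrough codons before the
    stop.
    """
    if fs_convention not in ("stop_included", "stop_excluded"):
        raise ValueError(f"unknown fs convention {fs_convention!r}")
    m = _PROT.match(text.strip())
    if m is None:
        raise HgvsParseError(f"not a truncating protein change: {text!r}")
    pos = int(m.group("pos"))
    if m.group("star"):
        return ProteinTruncation(
            kind="nonsense", changed_residue=pos,
            fs_stop_offset=None, last_intact_aa=pos - 1,
        )
    stop = int(m.group("stop"))
    if stop < 1:
        raise HgvsParseError(f"fs stop offset must be >= 1 in {text!r}")
    last = pos + stop - 2 if fs_convention == "stop_included" else pos + stop - 1
    return ProteinTruncation(
        kind="frameshift", changed_residue=pos,
        fs_stop_offset=stop, last_intact_aa=last,
    )
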