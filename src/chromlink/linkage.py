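"""Cross-database navigation URLs for lncRNA-peak-gene triads.

Builds the query URLs that jump from a triad in the peak database to the
graphical contact summary of the contact database: contacts of a given
lncRNA at a specific (optionally extended) locus, all contacts of the
lncRNA, or all RNAs contacting a locus.  The query-string layout follows
the published example byte-for-byte, including the fixed parameter order
(locus, name, rnaID, organism) and "+" for spaces in the organism name.
Only the locus mode's schema is published; the other two modes reuse the
same parameter vocabulary and are a reconstruction (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional
from urllib.parse import parse_qsl, urlsplit

from .colocalization import extend_interval
from .io_formats import GenomicInterval, format_locus, parse_locus

__all__ = [
    "DEFAULT_BASE",
    "EXTENSION_CHOICES",
    "TriadQuery",
    "build_rnachrom_url",
    "parse_rnachrom_url",
]

DEFAULT_BASE = "https://rnachrom2.bioinf.fbb.msu.ru"
_PATH = "basic_graphical_summary_dna_filter"

#: Locus-extension menu, bases (1 / 5 / 10 / 25 / 50 / 100 kb).
EXTENSION_CHOICES: tuple[int, ...] = (1_000, 5_000, 10_000, 25_000, 50_000, 100_000)

_MODES = {"locus_contacts", "all_contacts", "all_rnas_at_locus"}


@dataclass(frozen=True)
class TriadQuery:
    """Parameters of one navigation request.

    extension
        One of :data:`EXTENSION_CHOICES` (bases) or None; applied to the
        locus before rendering, with the display start clamped at 1.
    mode
        ``locus_contacts`` — contacts of the lncRNA at the locus (requires
        locus); ``all_contacts`` — genome-wide contacts of the lncRNA;
        ``all_rnas_at_locus`` — every RNA contacting the locus.
    """

    lncrna_name: str
    rna_internal_id: str
    organism: str = "Homo sapiens"
    locus: Optional[GenomicInterval] = None
    extension: Optional[int] = None
    mode: str = "locus_contacts"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in {"locus_contacts", "all_rnas_at_locus"} and self.locus is None:
            raise ValueError(f"mode {self.mode!r} requires a locus")
        if self.extension is not None:
            if self.locus is None:
                raise ValueError("extension is only meaningful with a locus")
            if self.extension not in EXTENSION_CHOICES:
                raise ValueError(
                    f"extension must be one of {EXTENSION_CHOICES}, got {self.extension}"
                )


def _require(value: str, name: str) -> str:
    if not value:
        raise ValueError(f"missing required field: {name}")
    return value


def build_rnachrom_url(q: TriadQuery, base: str = DEFAULT_BASE) -> str:
    """Render a :class:`TriadQuery` as a contact-database URL.

    Parameter order is fixed (locus, name, rnaID, organism); the locus is
    written in 1-based display form after any extension; organism spaces
    become "+" to match the published URL byte-for-byte.
    """
    params: list[tuple[str, str]] = []
    if q.mode != "all_contacts":
        assert q.locus is not None
        locus = extend_interval(q.locus, q.extension) if q.extension else q.locus
        params.append(("locus", format_locus(locus)))
    if q.mode != "all_rnas_at_locus":
        params.append(("name", _require(q.lncrna_name, "lncrna_name")))
        params.append(("rnaID", _require(q.rna_internal_id, "rna_internal_id")))
    params.append(("organism", _require(q.organism, "organism").replace(" ", "+")))
    query = "&".join(f"{k}={v}" for k, v in params)
    return f"{base.rstrip('/')}/{_PATH}?{query}"


def parse_rnachrom_url(url: str) -> TriadQuery:
    """Invert :func:`build_rnachrom_url`.

    The returned query carries the (already extended) locus and
    ``extension=None``; the mode is inferred from which parameters are
    present.
    """
    parts = urlsplit(url)
    params = dict(parse_qsl(parts.query))
    locus = parse_locus(params["locus"]) if "locus" in params else None
    has_rna = "name" in params or "rnaID" in params
    if locus is None:
        mode = "all_contacts"
    elif not has_rna:
        mode = "all_rnas_at_locus"
    else:
        mode = "locus_contacts"
    return TriadQuery(
        lncrna_name=params.get("name", ""),
        rna_internal_id=params.get("rnaID", ""),
        organism=params.get("organism", ""),
        locus=locus,
        extension=None,
        mode=mode,
    )
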