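"""Named Y-STR marker sets.

Multi-copy markers (DYS385, DYF387S1) are represented as two columns with
``a``/``b`` suffixes; capillary electrophoresis cannot phase the two copies,
so column assignment is a convention (see :mod:`ystrpop.data_io`).
"""

from __future__ import annotations

#: The 17-locus Yfiler panel.
YFILER17: tuple[str, ...] = (
    "DYS19",
    "DYS385a",
    "DYS385b",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "YGATAH4",
)

#: The 27-locus Yfiler Plus panel (Yfiler plus ten additional loci).
YFILER_PLUS27: tuple[str, ...] = YFILER17 + (
    "DYF387S1a",
    "DYF387S1b",
    "DYS449",
    "DYS460",
    "DYS481",
    "DYS518",
    "DYS533",
    "DYS570",
    "DYS576",
    "DYS627",
)

MARKER_SETS: dict[str, tuple[str, ...]] = {
    "yfiler17": YFILER17,
    "yfilerplus27": YFILER_PLUS27,
}


def resolve_marker_set(name_or_loci: str | list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Resolve a named marker set or pass through an explicit locus list."""
    if isinstance(name_or_loci, str):
        try:
            return MARKER_SETS[name_or_loci]
        except KeyError:
            raise ValueError(
                f"unknown marker set {name_or_loci!r}; valid names: "
                f"{sorted(MARKER_SETS)} (or pass an explicit locus list)"
            ) from None
    return tuple(name_or_loci)
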