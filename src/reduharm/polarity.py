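"""Ionization polarity vocabulary shared by the metadata and raw-data layers.

Polarity is recorded per spectrum in mzML/mzXML scan headers and per
analysis in repository metadata; the two observations are reconciled by the
record linker when a study deposited several analyses.
"""

from __future__ import annotations

import enum


class Polarity(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNSPECIFIED = "unspecified"
    UNKNOWN = "unknown"  # per-scan value when the header carries none

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Accepted spellings of ionization mode in deposited metadata, all matched
#: case-insensitively. Extend via :func:`parse_polarity_label`'s ``extra``.
_POSITIVE_LABELS = {"positive", "pos", "esi+", "positive ion mode", "+"}
_NEGATIVE_LABELS = {"negative", "neg", "esi-", "esi−", "negative ion mode", "-"}


def parse_polarity_label(label: str | None, extra: dict[str, Polarity] | None = None) -> Polarity:
    """Map a free-text ion-mode label onto the controlled polarity enum.

    Unrecognized labels map to ``UNSPECIFIED`` rather than raising: an
    analysis without a usable polarity simply cannot participate in
    polarity-based disambiguation.
    """
    if label is None:
        return Polarity.UNSPECIFIED
    key = label.strip().lower()
    if not key:
        return Polarity.UNSPECIFIED
    if extra and key in extra:
        return extra[key]
    if key in _POSITIVE_LABELS:
        return Polarity.POSITIVE
    if key in _NEGATIVE_LABELS:
        return Polarity.NEGATIVE
    return Polarity.UNSPECIFIED
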