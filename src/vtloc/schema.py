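"""The 21-landmark vocabulary of the midsagittal vocal-tract area.

Articulatory studies of the vocal tract annotate a fixed catalogue of 21
anatomical points on each midsagittal image: characteristic points of the
speech articulators (e.g. the tongue tip) or junctions between them (e.g.
the tongue--epiglottis junction).  The catalogue below is ordered
alphabetically by abbreviation and that order is the canonical channel /
column / row order used everywhere in this package: heat-map channels,
annotation CSV columns and report rows all index landmarks by it.

Coordinate convention (used package-wide): ``x`` is the column index,
``y`` is the row index, both 0-based with the origin at the centre of the
top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


@dataclass(frozen=True)
class SchemaEntry:
    """One named anatomical landmark."""

    abbreviation: str
    name: str
    description: str


@dataclass(frozen=True)
class LandmarkSchema:
    """Ordered, immutable catalogue of landmark definitions.

    The order of ``entries`` is a total order reused verbatim by heat-map
    channels, annotation columns and report rows.
    """

    entries: tuple[SchemaEntry, ...]

    def __post_init__(self) -> None:
        abbrs = [e.abbreviation for e in self.entries]
        if len(set(abbrs)) != len(abbrs):
            raise ValueError("landmark abbreviations must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SchemaEntry]:
        return iter(self.entries)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(e.abbreviation for e in self.entries)

    def index(self, abbreviation: str) -> int:
        """0-based position of ``abbreviation`` in the canonical order."""
        try:
            return self.abbreviations.index(abbreviation)
        except ValueError:
            raise KeyError(f"unknown landmark abbreviation: {abbreviation!r}") from None

    def entry(self, abbreviation: str) -> SchemaEntry:
        return self.entries[self.index(abbreviation)]


_TABLE: tuple[tuple[str, str, str], ...] = (
    ("ANS", "Anterior Nasal Spine", "Anterior nasal spine"),
    ("EG", "Epiglottis-Glottis", "Junction between the epiglottis and the glottis"),
    ("ET", "Epiglottis Tip", "Tip of the epiglottis"),
    ("LC", "Lip-Chin", "Labiomental groove"),
    ("LLSV", "Lower Lip Skin Vermillion", "Vermillon border of the lower lip"),
    ("LLV", "Lower Lip Vermillion",
     "Junction between the wet and dry vermillion of the lower lip"),
    ("LT", "Lower Teeth", "Upper point of the lower incisors"),
    ("N", "Nose", "Most anterior point of the tip of the nose"),
    ("NM", "Neck-Mandible",
     "Junction between the horizontal submandibular line and vertical neck line"),
    ("NP", "Nose-Philtrum", "Junction between the philtrum and the external nose"),
    ("NPX", "Nasopharynx", "Upper point of the nasopharynx"),
    ("PL", "Pharynx-Larynx",
     "Junction between the pharyngeal wall and the posterior supraglottic region"),
    ("PNS", "Posterior Nasal Spine", "Posterior nasal spine"),
    ("TE", "Tongue-Epiglottis", "Junction between the tongue and the epiglottis"),
    ("TJ", "Tongue-Jaw", "Junction between the tongue and the jaw"),
    ("TS", "Tongue Sub", "Most posterior point of the sublingual cavity"),
    ("TT", "Tongue Tip", "Tip of the tongue"),
    ("ULPV", "Upper Lip Philtrum Vermillion", "Vermillon border of the upper lip"),
    ("ULV", "Upper Lip Vermillion",
     "Junction between the wet and dry vermillion of the upper lip"),
    ("UT", "Upper Teeth", "Lower point of the upper incisors"),
    ("VT", "Velum Tip", "Tip of the velum"),
)

_SCHEMA = LandmarkSchema(tuple(SchemaEntry(*row) for row in _TABLE))


def load_schema() -> LandmarkSchema:
    """Return the fixed 21-entry vocal-tract landmark schema.

    The schema is a package constant; callers may rely on the order being
    identical across every call and every session.
    """
    return _SCHEMA
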