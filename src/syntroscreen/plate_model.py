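"""Core data types and microplate coordinate conventions.

The screen is run in standard SBS microplates (96-well: 8 rows x 12
columns; 384-well: 16 rows x 24 columns). Internally all coordinates are
0-based row-major integers; the canonical letter+number labels (``A1`` ..
``P24``) appear only at I/O boundaries. Time is modelled as hours
(floating point); the endpoint screen uses exactly {0, 48} but
growth-curve and fluorescence data may carry arbitrary grids.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field

PLATE_SHAPES: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"
_LABEL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")

FLUOROPHORES = frozenset({"none", "blue", "red"})
CONDITION_KINDS = frozenset({"blank", "monoculture", "coculture"})
FLAG_KINDS = frozenset(
    {"replicate_spread", "contamination", "positional_bias", "activity_range"}
)


class PlateFormatError(ValueError):
    """A well label or coordinate is invalid for the stated plate format."""


def plate_shape(plate_format: int) -> tuple[int, int]:
    """Return (n_rows, n_cols) for a 96- or 384-well plate."""
    try:
        return PLATE_SHAPES[int(plate_format)]
    except (KeyError, ValueError):
        raise PlateFormatError(f"unsupported plate format: {plate_format!r}")


def well_index(label: str, plate_format: int) -> tuple[int, int]:
    """Convert a canonical well label (e.g. ``'B7'``) to 0-based (row, col).

    Raises :class:`PlateFormatError` if the label falls outside the plate.
    """
    n_rows, n_cols = plate_shape(plate_format)
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise PlateFormatError(f"malformed well label: {label!r}")
    row = _ROW_LETTERS.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if row >= n_rows or col < 0 or col >= n_cols:
        raise PlateFormatError(
            f"well {label!r} out of range for {plate_format}-well plate"
        )
    return row, col


def well_label(row: int, col: int, plate_format: int) -> str:
    """Inverse of :func:`well_index`: 0-based (row, col) to canonical label."""
    n_rows, n_cols = plate_shape(plate_format)
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise PlateFormatError(
            f"coordinates ({row}, {col}) out of range for {plate_format}-well plate"
        )
    return f"{_ROW_LETTERS[row]}{col + 1}"


def is_edge(row: int, col: int, plate_format: int) -> bool:
    """True iff the well lies on the plate perimeter."""
    n_rows, n_cols = plate_shape(plate_format)
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise PlateFormatError(
            f"coordinates ({row}, {col}) out of range for {plate_format}-well plate"
        )
    return row == 0 or col == 0 or row == n_rows - 1 or col == n_cols - 1


@dataclass(frozen=True)
class StrainRecord:
    """One screened strain: its deleted gene and role in the assay.

    ``is_reference`` marks the prototrophic control (no deletion);
    ``fluorophore`` records an optional BFP/mScarlet-style tag used by the
    population-dynamics assays.
    """

    strain_id: str
    deleted_gene: str = ""
    is_reference: bool = False
    fluorophore: str = "none"

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        if self.fluorophore not in FLUOROPHORES:
            raise ValueError(f"fluorophore must be one of {sorted(FLUOROPHORES)}")
        if self.is_reference and self.deleted_gene:
            raise ValueError("a reference (prototrophic) strain has no deleted gene")


@dataclass(frozen=True)
class Condition:
    """A well condition: blank, monoculture or pairwise coculture."""

    condition_id: str
    kind: str
    strains: tuple[str, ...] = ()
    inoculation_ratio: tuple[float, float] | None = None
    media: str = "SM"

    def __post_init__(self) -> None:
        if self.kind not in CONDITION_KINDS:
            raise ValueError(f"kind must be one of {sorted(CONDITION_KINDS)}")
        expected = {"blank": 0, "monoculture": 1, "coculture": 2}[self.kind]
        object.__setattr__(self, "strains", tuple(self.strains))
        if len(self.strains) != expected:
            raise ValueError(
                f"{self.kind} condition requires {expected} strain(s), "
                f"got {len(self.strains)}"
            )
        if self.kind == "coculture":
            if self.inoculation_ratio is None:
                raise ValueError("coculture condition requires inoculation_ratio")
            r1, r2 = self.inoculation_ratio
            if not (r1 > 0 and r2 > 0):
                raise ValueError("inoculation_ratio components must be > 0")
        elif self.inoculation_ratio is not None:
            raise ValueError("inoculation_ratio only applies to cocultures")


@dataclass
class WellObservation:
    """Raw readings from one well: OD600 by time, optional fluorescence.

    ``od600`` maps time in hours to the reading; ``fluorescence`` maps
    channel name ('blue'/'red') to a time->intensity map.
    """

    plate_id: str
    batch: str
    row: int
    col: int
    condition_id: str = ""
    od600: dict[float, float] = field(default_factory=dict)
    fluorescence: dict[str, dict[float, float]] | None = None

    def label(self, plate_format: int) -> str:
        return well_label(self.row, self.col, plate_format)


@dataclass(frozen=True)
class QCFlag:
    """One quality-control flag, scoped to a well or a whole assay.

    ``hard`` flags gate inclusion downstream; soft flags (e.g. the
    neighbourhood warning around a contaminated well) are advisory only.
    """

    flag_kind: str
    scope: str  # 'well' or 'assay'
    detail: str = ""
    plate_id: str = ""
    well: str = ""
    condition_id: str = ""
    hard: bool = True

    def __post_init__(self) -> None:
        if self.flag_kind not in FLAG_KINDS:
            raise ValueError(f"flag_kind must be one of {sorted(FLAG_KINDS)}")
        if self.scope not in ("well", "assay"):
            raise ValueError("scope must be 'well' or 'assay'")


@dataclass
class Config:
    """All pipeline thresholds in one place.

    auxotroph_fraction_threshold : growth below this fraction of the
        prototrophic parent's OD in minimal medium classifies a strain as
        auxotrophic (strict ``<``), default 0.2.
    sc_growth_threshold : minimum fraction of parent growth on complete
        medium required to count as 'grows well on SC', default 0.5.
    fc_threshold : fold-difference gate, coculture vs fittest constituent
        monoculture, default 1.5.
    alpha : adjusted-p cutoff for hit calls, default 0.05.
    z_threshold : minimum Z-factor (coculture vs fittest monoculture) for
        an adequate activity range, default 0.5.
    mad_k, mad_scale : robust replicate-spread gate |x - med| > k*scale*MAD,
        with scale 1.4826 making MAD consistent with sigma under normality.
    blank_margin : growth above this in a blank or strict-auxotroph well
        indicates contamination; also the floor for robust-MAD thresholds
        on plates whose residual spread collapses to zero. Default 0.05 OD.
    edge_bias_k : multiplier for the positional-bias tests, default 3.
    fd_floor : denominator floor for fold differences, default 1e-3 OD.
    inoculum_od : total OD600-equivalents seeded per well, default 0.1.
    normalization_od : OD to which input plates are normalized before
        pinning, default 2.5 (recorded for provenance; not used in math).
    stability_tolerance : max |final proportion difference| between serial
        passages to call a composition 're-established', default 0.15.
    """

    auxotroph_fraction_threshold: float = 0.2
    sc_growth_threshold: float = 0.5
    fc_threshold: float = 1.5
    alpha: float = 0.05
    z_threshold: float = 0.5
    mad_k: float = 3.0
    mad_scale: float = 1.4826
    blank_margin: float = 0.05
    edge_bias_k: float = 3.0
    fd_floor: float = 1e-3
    inoculum_od: float = 0.1
    normalization_od: float = 2.5
    stability_tolerance: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "auxotroph_fraction_threshold",
            "sc_growth_threshold",
            "fc_threshold",
            "z_threshold",
            "mad_k",
            "mad_scale",
            "blank_margin",
            "edge_bias_k",
            "fd_floor",
            "inoculum_od",
            "normalization_od",
            "stability_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]
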