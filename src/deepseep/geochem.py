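"""Hydrocarbon gas and liquid geochemistry summaries and origin classification.

Gas-phase measurements from sediment piston cores (total alkane gas, the
C2+ alkane fraction, and the stable carbon isotope composition of methane)
support a standard origin diagnosis: microbially produced methane is very
dry (high Bernard ratio C1/(C2+C3)) and strongly depleted in 13C, while
thermogenic gas carries substantial C2+ alkanes and heavier isotope
signatures.  The classifier applies the conventional Bernard-diagram bands:

* biogenic:     C1/(C2+C3) > 1000  and  d13C-CH4 < -60 permil (vs PDB)
* thermogenic:  C1/(C2+C3) < 100   and  d13C-CH4 > -50 permil

Both criteria firing on opposite sides yields ``mixed``; a single line of
evidence, or values between the bands, yields ``indeterminate``.  Only the
biogenic band is taken from the deep-sea survey this package mirrors; the
thermogenic band is the conventional literature extension and both are
configurable.

Liquid-phase summaries cover the C15-C34 n-alkane sum and the unresolved
complex mixture (UCM) flag indicating degraded petroleum.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import pandas as pd


class Origin(str, Enum):
    BIOGENIC = "biogenic"
    THERMOGENIC = "thermogenic"
    MIXED = "mixed"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class GasProfile:
    """Gas measurements for one site (ppm by volume; d13C in permil vs PDB)."""

    site_id: str
    total_alkane_gas_ppm: float | None = None
    c2plus_ppm: float | None = None
    c1_ppm: float | None = None
    c2_ppm: float | None = None
    c3_ppm: float | None = None
    delta13C_CH4: float | None = None

    def __post_init__(self) -> None:
        for name in ("total_alkane_gas_ppm", "c2plus_ppm", "c1_ppm", "c2_ppm", "c3_ppm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if (
            self.total_alkane_gas_ppm is not None
            and self.c2plus_ppm is not None
            and self.c2plus_ppm > self.total_alkane_gas_ppm
        ):
            warnings.warn(
                f"site {self.site_id}: C2+ ({self.c2plus_ppm} ppm) exceeds total alkane gas "
                f"({self.total_alkane_gas_ppm} ppm)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OriginThresholds:
    """Bernard-diagram classification bands (configurable)."""

    biogenic_min_ratio: float = 1000.0
    biogenic_max_delta13C: float = -60.0
    thermogenic_max_ratio: float = 100.0
    thermogenic_min_delta13C: float = -50.0


@dataclass(frozen=True)
class OriginCall:
    """Classification outcome with the evidence lines that produced it."""

    site_id: str
    label: Origin
    bernard_ratio: float | None = None
    delta13C: float | None = None
    evidence: tuple[str, ...] = ()


def approximate_methane(profile: GasProfile) -> float:
    """Methane approximation: total alkane gas minus C2+ alkanes (ppm).

    Negative differences (measurement inconsistency) are floored at zero
    with a warning.
    """
    if profile.total_alkane_gas_ppm is None or profile.c2plus_ppm is None:
        raise ValueError(
            f"site {profile.site_id}: methane approximation needs total_alkane_gas_ppm and c2plus_ppm"
        )
    diff = profile.total_alkane_gas_ppm - profile.c2plus_ppm
    if diff < 0:
        warnings.warn(
            f"site {profile.site_id}: C2+ exceeds total alkane gas; flooring methane at 0 ppm",
            stacklevel=2,
        )
        return 0.0
    return diff


def bernard_ratio(c1_ppm: float, c2_ppm: float, c3_ppm: float) -> float:
    """Bernard ratio C1/(C2+C3); undefined (raises) when C2+C3 = 0."""
    denom = c2_ppm + c3_ppm
    if denom <= 0:
        raise ValueError("C2 + C3 is zero: Bernard ratio undefined (report as NA)")
    return c1_ppm / denom


def _ratio_vote(ratio, t: OriginThresholds) -> tuple[str, Origin | None]:
    if ratio is None:
        return "C1/(C2+C3) not available", None
    if ratio > t.biogenic_min_ratio:
        return f"C1/(C2+C3) = {ratio:g} > {t.biogenic_min_ratio:g} (biogenic band)", Origin.BIOGENIC
    if ratio < t.thermogenic_max_ratio:
        return f"C1/(C2+C3) = {ratio:g} < {t.thermogenic_max_ratio:g} (thermogenic band)", Origin.THERMOGENIC
    return f"C1/(C2+C3) = {ratio:g} between bands", None


def _delta_vote(delta13C, t: OriginThresholds) -> tuple[str, Origin | None]:
    if delta13C is None:
        return "d13C-CH4 not available", None
    if delta13C < t.biogenic_max_delta13C:
        return (f"d13C-CH4 = {delta13C:g} < {t.biogenic_max_delta13C:g} permil (biogenic band)",
                Origin.BIOGENIC)
    if delta13C > t.thermogenic_min_delta13C:
        return (f"d13C-CH4 = {delta13C:g} > {t.thermogenic_min_delta13C:g} permil (thermogenic band)",
                Origin.THERMOGENIC)
    return f"d13C-CH4 = {delta13C:g} permil between bands", None


def classify_gas_origin(
    ratio: float | None,
    delta13C: float | None,
    site_id: str = "",
    thresholds: OriginThresholds | None = None,
) -> OriginCall:
    """Classify gas origin from the Bernard ratio and methane d13C.

    ``biogenic``/``thermogenic`` require both lines of evidence to agree in
    the respective band; opposing evidence yields ``mixed``; a single line
    of evidence or between-band values yield ``indeterminate``.
    """
    t = thresholds or OriginThresholds()
    ratio_ev, ratio_vote = _ratio_vote(ratio, t)
    delta_ev, delta_vote = _delta_vote(delta13C, t)
    evidence = [ratio_ev, delta_ev]
    if ratio_vote is not None and ratio_vote == delta_vote:
        label = ratio_vote
    elif ratio_vote is not None and delta_vote is not None:
        label = Origin.MIXED
    else:
        label = Origin.INDETERMINATE
    return OriginCall(site_id=site_id, label=label, bernard_ratio=ratio, delta13C=delta13C,
                      evidence=tuple(evidence))


_CARBON_RE = re.compile(r"^C?(\d+)$")


def _carbon_number(label) -> int:
    if isinstance(label, (int, float)) and not isinstance(label, bool):
        if float(label).is_integer():
            return int(label)
        raise ValueError(f"non-integer carbon number {label!r}")
    m = _CARBON_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"unlabeled or malformed carbon-number row: {label!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class AlkaneSummary:
    sum_n_alkanes_ng_g: float
    ucm_flag: bool
    c2plus_ppm: float | None = None  # gas-phase pass-through metadata


def alkane_summary(
    liquid_table: pd.DataFrame,
    ucm_ug_g: float | None = None,
    c2plus_ppm: float | None = None,
    carbon_min: int = 15,
    carbon_max: int = 34,
) -> AlkaneSummary:
    """Sum n-alkane concentrations over C15-C34 and flag UCM occurrence.

    ``liquid_table`` needs columns ``carbon_number`` (ints or ``"C15"``-style
    labels) and ``conc_ng_g``.  Rows outside [carbon_min, carbon_max] are
    excluded; unlabeled rows raise.
    """
    if liquid_table.empty:
        return AlkaneSummary(0.0, bool(ucm_ug_g and ucm_ug_g > 0), c2plus_ppm)
    for col in ("carbon_number", "conc_ng_g"):
        if col not in liquid_table.columns:
            raise ValueError(f"liquid alkane table lacks column {col!r}")
    if liquid_table["carbon_number"].isna().any():
        raise ValueError("unlabeled rows in liquid alkane table")
    numbers = liquid_table["carbon_number"].map(_carbon_number)
    in_range = numbers.between(carbon_min, carbon_max)
    total = float(liquid_table.loc[in_range, "conc_ng_g"].sum())
    return AlkaneSummary(total, bool(ucm_ug_g and ucm_ug_g > 0), c2plus_ppm)


def read_gas_tsv(path) -> list[GasProfile]:
    """Read a site gas-geochemistry TSV into :class:`GasProfile` rows."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for _, row in df.iterrows():
        def val(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        profiles.append(
            GasProfile(
                site_id=str(row["site_id"]),
                total_alkane_gas_ppm=val("total_alkane_gas_ppm"),
                c2plus_ppm=val("c2plus_ppm"),
                c1_ppm=val("c1_ppm"),
                c2_ppm=val("c2_ppm"),
                c3_ppm=val("c3_ppm"),
                delta13C_CH4=val("d13C_CH4_permil"),
            )
        )
    return profiles
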