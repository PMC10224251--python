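"""Qualitative bioclimatic diagnosis (isobioclimates).

An isobioclimate is the combination macrobioclimate + bioclimate + variant +
thermotype horizon + ombrotype horizon + continentality class. Threshold
tables ship as a versioned YAML config (:func:`default_tables`) with values
from the Rivas-Martinez 2011 worldwide system; every interval is lower-closed,
upper-open, and each class splits into two horizons at its midpoint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .indices import BioclimVector, MonthlyClimatology, summer_quarter

__all__ = [
    "BEYOND_TABLE",
    "ThresholdTables",
    "IsobioclimateDiagnosis",
    "default_tables",
    "macrobioclimate_test",
    "classify_axis",
    "diagnose",
    "species_isobioclimate_summary",
]

#: Marker returned when a value falls outside the configured table span.
BEYOND_TABLE = "beyond-table"


@dataclass(frozen=True)
class AxisTable:
    """One classification axis: ordered (name, lo, hi) intervals + horizon rule."""

    variable: str
    classes: tuple[tuple[str, float, float], ...]
    horizon_labels: tuple[str, str]
    high_value_horizon: str

    def __post_init__(self) -> None:
        prev_hi = None
        for name, lo, hi in self.classes:
            if hi <= lo:
                raise ValueError(f"axis {self.variable}: empty interval for {name}")
            if prev_hi is not None and not np.isclose(lo, prev_hi):
                raise ValueError(f"axis {self.variable}: gap/overlap before {name}")
            prev_hi = hi
        if self.high_value_horizon not in self.horizon_labels:
            raise ValueError(f"axis {self.variable}: bad high_value_horizon")

    def classify(self, value: float) -> tuple[str, str]:
        """(class, horizon) containing ``value``, or the beyond-table marker."""
        if not np.isfinite(value):
            return BEYOND_TABLE, BEYOND_TABLE
        for name, lo, hi in self.classes:
            if lo <= value < hi:
                mid = 0.5 * (lo + hi)
                low_label = (
                    self.horizon_labels[0]
                    if self.horizon_labels[1] == self.high_value_horizon
                    else self.horizon_labels[1]
                )
                horizon = self.high_value_horizon if value >= mid else low_label
                return name, horizon
        return BEYOND_TABLE, BEYOND_TABLE


@dataclass(frozen=True)
class ThresholdTables:
    """All configured classification tables plus scalar rule parameters."""

    ombrotype: AxisTable
    continentality: AxisTable
    thermotype_mediterranean: AxisTable
    thermotype_temperate: AxisTable
    thermotype_mediterranean_tp: AxisTable
    thermotype_temperate_tp: AxisTable
    med_regimes: tuple[tuple[str, float, float], ...]
    med_oceanic_ic_max: float
    temperate_classes: tuple[tuple[str, float, float], ...]
    itc_validity_floor: float
    submediterranean_ios3_max: float
    version: int = 1


def _axis_from_cfg(cfg: dict, key: str = "classes") -> AxisTable:
    return AxisTable(
        variable=cfg["variable"],
        classes=tuple((c["name"], float(c["lo"]), float(c["hi"])) for c in cfg[key]),
        horizon_labels=tuple(cfg["horizon_labels"]),
        high_value_horizon=cfg["high_value_horizon"],
    )


def load_tables(path=None) -> ThresholdTables:
    """Load and validate threshold tables from YAML (package default if None)."""
    if path is None:
        text = resources.files("isoclim.data").joinpath("thresholds.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    axes = cfg["axes"]
    med = axes["thermotype_mediterranean"]
    temp = axes["thermotype_temperate"]

    def tp_axis(base: dict) -> AxisTable:
        return AxisTable(
            variable="tp",
            classes=tuple((c["name"], float(c["lo"]), float(c["hi"])) for c in base["tp_classes"]),
            horizon_labels=tuple(base["horizon_labels"]),
            high_value_horizon=base["high_value_horizon"],
        )

    return ThresholdTables(
        ombrotype=_axis_from_cfg(axes["ombrotype"]),
        continentality=_axis_from_cfg(axes["continentality"]),
        thermotype_mediterranean=_axis_from_cfg(med),
        thermotype_temperate=_axis_from_cfg(temp),
        thermotype_mediterranean_tp=tp_axis(med),
        thermotype_temperate_tp=tp_axis(temp),
        med_regimes=tuple(
            (c["name"], float(c["lo"]), float(c["hi"]))
            for c in cfg["bioclimate"]["mediterranean"]["regimes"]
        ),
        med_oceanic_ic_max=float(cfg["bioclimate"]["mediterranean"]["oceanic_ic_max"]),
        temperate_classes=tuple(
            (c["name"], float(c["lo"]), float(c["hi"]))
            for c in cfg["bioclimate"]["temperate"]["classes"]
        ),
        itc_validity_floor=float(cfg["itc_validity_floor"]),
        submediterranean_ios3_max=float(cfg["submediterranean_ios3_max"]),
        version=int(cfg.get("version", 1)),
    )


_DEFAULT: ThresholdTables | None = None


def default_tables() -> ThresholdTables:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_tables()
    return _DEFAULT


@dataclass
class IsobioclimateDiagnosis:
    """Qualitative diagnosis of one location's climate."""

    macrobioclimate: str
    variant: str
    bioclimate: str
    continentality: str
    thermotype_horizon: str
    ombrotype_horizon: str

    def label(self) -> str:
        """Full isobioclimate string in field order."""
        parts = [self.bioclimate]
        if self.variant != "none":
            parts.append(self.variant)
        parts += [self.continentality, self.thermotype_horizon, self.ombrotype_horizon]
        return " ".join(parts)


def macrobioclimate_test(
    c: MonthlyClimatology, mode: str = "consecutive", quarter_mode: str = "warmest"
) -> str:
    """Mediterranean vs Temperate from summer drought.

    ``consecutive`` (default): Mediterranean iff two consecutive summer-quarter
    months each satisfy ``Pi < 2 * Ti``. ``two_hottest_mean``: Mediterranean iff
    the two hottest summer months satisfy ``mean(P) < 2 * mean(T)``.
    """
    q = summer_quarter(c, mode=quarter_mode)
    if mode == "consecutive":
        for a, b in zip(q[:-1], q[1:]):
            if c.p[a] < 2.0 * c.t[a] and c.p[b] < 2.0 * c.t[b]:
                return "Mediterranean"
        return "Temperate"
    if mode == "two_hottest_mean":
        order = sorted(q, key=lambda m: (-c.t[m], m))[:2]
        p_mean = float(np.mean(c.p[order]))
        t_mean = float(np.mean(c.t[order]))
        return "Mediterranean" if p_mean < 2.0 * t_mean else "Temperate"
    raise ValueError(f"unknown macrobioclimate mode {mode!r}")


def classify_axis(value: float, axis: AxisTable) -> tuple[str, str]:
    """(class, horizon) for ``value`` on one axis; beyond-table marker outside."""
    return axis.classify(value)


def _interval_lookup(value: float, classes) -> str:
    for name, lo, hi in classes:
        if lo <= value < hi:
            return name
    return BEYOND_TABLE


def diagnose(
    v: BioclimVector,
    c: MonthlyClimatology,
    tables: ThresholdTables | None = None,
    macro_mode: str = "consecutive",
) -> IsobioclimateDiagnosis:
    """Full qualitative diagnosis of one bioclimatic vector.

    Thermotype uses Itc (It-compensated) unless it falls below the configured
    validity floor, in which case the positive-temperature (Tp) sub-table
    applies. The submediterranean variant flags Temperate diagnoses whose
    summer-quarter ombrothermic index falls below the configured cut.
    """
    tables = tables or default_tables()
    macro = macrobioclimate_test(c, mode=macro_mode)

    cont_class, cont_hor = tables.continentality.classify(v.ic)
    ombro_class, ombro_hor = tables.ombrotype.classify(v.io)

    if macro == "Mediterranean":
        regime = _interval_lookup(v.io, tables.med_regimes)
        ocean = "oceanic" if v.ic < tables.med_oceanic_ic_max else "continental"
        bioclimate = f"Mediterranean {regime} {ocean}"
        itc_axis, tp_axis = tables.thermotype_mediterranean, tables.thermotype_mediterranean_tp
        variant = "none"
    else:
        ocean = _interval_lookup(v.ic, tables.temperate_classes)
        bioclimate = f"Temperate {ocean}"
        itc_axis, tp_axis = tables.thermotype_temperate, tables.thermotype_temperate_tp
        variant = (
            "submediterranean"
            if np.isfinite(v.ios3) and v.ios3 < tables.submediterranean_ios3_max
            else "none"
        )

    if np.isfinite(v.itc) and v.itc >= tables.itc_validity_floor:
        th_class, th_hor = itc_axis.classify(v.itc)
    else:
        th_class, th_hor = tp_axis.classify(v.tp)

    def fmt(cls: str, hor: str) -> str:
        return cls if cls == BEYOND_TABLE else f"{hor} {cls}"

    return IsobioclimateDiagnosis(
        macrobioclimate=macro,
        variant=variant,
        bioclimate=bioclimate,
        continentality=fmt(cont_class, cont_hor),
        thermotype_horizon=fmt(th_class, th_hor),
        ombrotype_horizon=fmt(ombro_class, ombro_hor),
    )


def species_isobioclimate_summary(
    diagnoses: list[IsobioclimateDiagnosis], rarity_fraction: float = 0.05
) -> list[dict]:
    """Distinct isobioclimates ranked by frequency.

    Entries whose share is at or below ``rarity_fraction`` are marked
    ``parenthetical`` (a taxon occurring there only ad hoc). Ties sort by
    count (descending) then label (lexicographic).
    """
    if not diagnoses:
        raise ValueError("at least one diagnosis required")
    counts = Counter(d.label() for d in diagnoses)
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        {
            "isobioclimate": label,
            "count": n,
            "fraction": n / total,
            "parenthetical": (n / total) <= rarity_fraction,
        }
        for label, n in ranked
    ]
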