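"""Aggregate the six developability metrics and flag them against a
clinical-stage calibration distribution.

The six metrics are: total CDR length, CDR3 length, CDR3 compactness, and
the three surface patch scores (hydrophobicity PSH, positive charge PPC,
negative charge PNC).  Each metric of a candidate is placed on the
empirical distribution of a reference panel of clinical-stage molecules:

* **red** -- the value lies strictly outside the observed reference range;
* **amber** -- inside the range but within the lowest or highest 5 %
  (midrank empirical percentile) of the distribution;
* **green** -- otherwise.

The package ships no clinical reference values; distributions are built
from whatever reference CSV the user supplies (or from synthetic panels
for testing), so thresholds update automatically as the panel grows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import cdr_geometry, surface_metrics
from .errors import CalibrationError, ConfigurationError, InputError
from .structure_io import NanobodyStructure

METRICS = ("total_cdr_length", "cdr3_length", "cdr3_compactness", "psh", "ppc", "pnc")

Flag = Literal["green", "amber", "red"]

REFERENCE_COLUMNS = ("molecule_id",) + METRICS


@dataclass(frozen=True)
class ProfilerConfig:
    """Every tunable constant behind the six metrics, echoed in reports."""

    sasa_probe: float = 1.4          # A, water-sized rolling probe
    sasa_points: int = 960           # quadrature points per atom
    vicinity_cutoff: float = 4.0     # A, CDR-contact distance
    exposure_threshold: float = 0.075  # relative SASA for "surface"
    patch_radius: float = 7.5        # A, patch pair cutoff
    compactness_threshold: float = 1.25
    hydrophobicity_scale: str = "kyte-doolittle[1,2]"

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MetricProfile:
    """The six structure-derived developability metrics of one molecule."""

    total_cdr_length: int
    cdr3_length: int
    cdr3_compactness: float
    psh: float
    ppc: float
    pnc: float

    def __getitem__(self, metric: str) -> float:
        if metric not in METRICS:
            raise KeyError(metric)
        return getattr(self, metric)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


@dataclass
class ReferenceDistribution:
    """Observed values of one metric across the calibration panel."""

    metric: str
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise CalibrationError(
                f"reference for {self.metric} needs >= 2 values, got {self.values.size}")
        if not np.all(np.isfinite(self.values)):
            raise CalibrationError(f"non-finite reference values for {self.metric}")
        self._sorted = np.sort(self.values)

    @property
    def min(self) -> float:
        return float(self._sorted[0])

    @property
    def max(self) -> float:
        return float(self._sorted[-1])

    def percentile(self, value: float) -> float:
        """Midrank empirical percentile: (#below + 0.5 * #equal) / N."""
        below = np.searchsorted(self._sorted, value, side="left")
        upto = np.searchsorted(self._sorted, value, side="right")
        return float((below + 0.5 * (upto - below)) / self._sorted.size)


@dataclass(frozen=True)
class FlagPolicy:
    """Amber-tail fraction and sidedness of the amber test."""

    amber_tail: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.amber_tail < 0.5:
            raise ConfigurationError(f"amber_tail must be in (0, 0.5), got {self.amber_tail}")


@dataclass(frozen=True)
class MetricFlag:
    value: float
    percentile: float
    flag: Flag


@dataclass(frozen=True)
class FlagReport:
    """Per-metric values, percentiles and flags, plus flag counts."""

    metrics: dict[str, MetricFlag]
    config: dict

    def count(self, flag: Flag) -> int:
        return sum(1 for m in self.metrics.values() if m.flag == flag)

    @property
    def counts(self) -> dict[Flag, int]:
        return {f: self.count(f) for f in ("green", "amber", "red")}

    def as_dict(self) -> dict:
        return {
            "metrics": {
                name: {"value": mf.value, "percentile": mf.percentile, "flag": mf.flag}
                for name, mf in self.metrics.items()
            },
            "counts": self.counts,
            "config": self.config,
        }


def profile(s: NanobodyStructure, config: ProfilerConfig = ProfilerConfig()) -> MetricProfile:
    """Compute all six metrics for one structure (deterministic per config)."""
    try:
        geom = cdr_geometry.cdr3_compactness(s)
    except InputError as exc:
        raise type(exc)(f"cdr3_compactness: {exc}") from exc
    try:
        sasa = surface_metrics.compute_sasa(s, probe=config.sasa_probe,
                                            n_points=config.sasa_points)
        vicinity = surface_metrics.cdr_vicinity(
            s, sasa, cutoff=config.vicinity_cutoff,
            exposure_threshold=config.exposure_threshold)
        patches = surface_metrics.patch_scores(s, sasa, vicinity,
                                               radius=config.patch_radius)
    except InputError as exc:
        raise type(exc)(f"patch_scores: {exc}") from exc
    return MetricProfile(
        total_cdr_length=cdr_geometry.total_cdr_length(s),
        cdr3_length=geom.length,
        cdr3_compactness=geom.compactness,
        psh=patches.psh,
        ppc=patches.ppc,
        pnc=patches.pnc,
    )


def assign_flag(
    value: float,
    ref: ReferenceDistribution,
    policy: FlagPolicy = FlagPolicy(),
) -> MetricFlag:
    """Flag one value against one reference distribution.

    Red strictly outside the observed range (a value exactly at the min or
    max is *inside* the range, hence at most amber); amber within the tail
    fraction on either flagged side; green otherwise.
    """
    if not math.isfinite(value):
        raise InputError(f"non-finite metric value: {value}")
    pct = ref.percentile(value)
    if value < ref.min or value > ref.max:
        flag: Flag = "red"
    elif pct <= policy.amber_tail or (policy.two_sided and pct >= 1.0 - policy.amber_tail):
        flag = "amber"
    else:
        flag = "green"
    return MetricFlag(value=float(value), percentile=pct, flag=flag)


def calibrate(
    structures: Iterable[NanobodyStructure],
    config: ProfilerConfig = ProfilerConfig(),
    provenance: str = "",
) -> dict[str, ReferenceDistribution]:
    """Profile a calibration panel into one distribution per metric.

    Structures that fail profiling are reported with a warning and skipped;
    at least two must succeed.
    """
    rows: list[MetricProfile] = []
    failures: list[str] = []
    for s in structures:
        try:
            rows.append(profile(s, config))
        except InputError as exc:
            failures.append(f"{s.source_id or '?'}: {exc}")
    if failures:
        warnings.warn(
            f"{len(failures)} structure(s) failed profiling and were skipped: "
            + "; ".join(failures))
    if len(rows) < 2:
        raise CalibrationError(
            f"calibration needs >= 2 profileable structures, got {len(rows)}")
    return {
        m: ReferenceDistribution(m, np.array([r[m] for r in rows]), provenance)
        for m in METRICS
    }


def flag_report(
    p: MetricProfile,
    refs: dict[str, ReferenceDistribution],
    policy: FlagPolicy = FlagPolicy(),
    config: ProfilerConfig = ProfilerConfig(),
) -> FlagReport:
    """Flag all six metrics of a profile; refs must cover every metric."""
    missing = [m for m in METRICS if m not in refs]
    if missing:
        raise ConfigurationError(f"reference missing metrics: {', '.join(missing)}")
    flags = {m: assign_flag(p[m], refs[m], policy) for m in METRICS}
    cfg = dict(config.as_dict(), amber_tail=policy.amber_tail, two_sided=policy.two_sided)
    return FlagReport(metrics=flags, config=cfg)


def profiles_to_frame(profiles: dict[str, MetricProfile]) -> pd.DataFrame:
    rows = [{"molecule_id": mid, **p.as_dict()} for mid, p in profiles.items()]
    return pd.DataFrame(rows, columns=list(REFERENCE_COLUMNS))


def save_reference(refs: dict[str, ReferenceDistribution], path: str | Path,
                   molecule_ids: Sequence[str] | None = None) -> None:
    """Write the reference table as CSV (one row per molecule, one column
    per metric)."""
    n = len(next(iter(refs.values())).values)
    ids = list(molecule_ids) if molecule_ids is not None else [f"ref_{i+1:03d}" for i in range(n)]
    data = {"molecule_id": ids}
    for m in METRICS:
        if m not in refs:
            raise ConfigurationError(f"reference missing metric {m}")
        data[m] = refs[m].values
    pd.DataFrame(data).to_csv(path, index=False)


def load_reference(path: str | Path, provenance: str | None = None) -> dict[str, ReferenceDistribution]:
    """Read a reference CSV back into per-metric distributions."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read reference CSV {path}: {exc}") from exc
    missing = [c for c in METRICS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"reference CSV {path} missing columns: {', '.join(missing)}")
    prov = provenance if provenance is not None else str(path)
    return {m: ReferenceDistribution(m, df[m].to_numpy(dtype=float), prov) for m in METRICS}
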