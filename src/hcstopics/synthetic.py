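"""Synthetic HCS-like dose-response data with planted latent structure.

The real study's inputs — multi-endpoint high-content-screening (HCS)
measurements on cultured rat hepatocytes plus rat liver histopathology
labels — are proprietary, so this module generates a stand-in with the
same shape and a known ground truth:

* 10 endpoints (8 distinct cellular assays, with Cell Loss and Nuclear
  Size duplicated across the two assay plates),
* 4 measurement time points (1, 6, 24, 48 h),
* a 10-point 2-fold dilution dose series topping out at 200 uM, with a
  matched DMSO vehicle control curve per (endpoint, time point),
* three planted drug classes — early-onset necrosis, late-onset
  necrosis, and non-necrotic — each of which activates one planted
  endpoint group on a documented schedule.

An "on" endpoint follows a monotone sigmoidal fold-of-control response
whose mean shift at the top dose equals ``effect_size`` times the
schedule multiplier; an "off" endpoint stays at the control baseline.
Gaussian measurement noise is added to every well-level value. The
ground truth (endpoint -> group map and class x time activation
schedule) ships with the dataset so recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FileFormatError
from .preprocess import CONTROL_DRUG_ID, DoseResponseCurve

CLASS_NECROSIS_EARLY = "necrosis_6h"
CLASS_NECROSIS_LATE = "necrosis_24h"
CLASS_NON_NECROSIS = "non_necrosis"
DEFAULT_CLASSES = (CLASS_NECROSIS_EARLY, CLASS_NECROSIS_LATE, CLASS_NON_NECROSIS)


@dataclass(frozen=True)
class EndpointSpec:
    """One assay endpoint with its plate and planted latent group."""

    name: str
    plate: int
    event_group: int

    def __post_init__(self) -> None:
        if self.plate not in (1, 2):
            raise ConfigurationError(f"endpoint {self.name}: plate must be 1 or 2")
        if self.event_group < 1:
            raise ConfigurationError(f"endpoint {self.name}: event_group must be >= 1")


# Default catalog: 8 distinct assays; Cell Loss and Nuclear Size are run on
# both plates and kept as separate terms, giving 10 endpoints. The planted
# groups pair severe-damage events (group 1), DNA Damage/Apoptosis (group 2)
# and the growth/regeneration readouts (group 3).
DEFAULT_ENDPOINTS: tuple[EndpointSpec, ...] = (
    EndpointSpec("Steatosis", plate=2, event_group=1),
    EndpointSpec("DNA Fragmentation", plate=1, event_group=1),
    EndpointSpec("Mitochondrial Potential", plate=2, event_group=1),
    EndpointSpec("Lysosome Mass", plate=1, event_group=1),
    EndpointSpec("DNA Damage", plate=1, event_group=2),
    EndpointSpec("Apoptosis", plate=1, event_group=2),
    EndpointSpec("Cell Loss (1)", plate=1, event_group=3),
    EndpointSpec("Cell Loss (2)", plate=2, event_group=3),
    EndpointSpec("Nuclear Size (1)", plate=1, event_group=3),
    EndpointSpec("Nuclear Size (2)", plate=2, event_group=3),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror the real study design: 122 drugs, time points
    1/6/24/48 h, a 10-point 2-fold titration up to 200 uM, and class
    fractions 15:8:22 (of 45) for early-necrosis, late-only-necrosis and
    non-necrotic drugs. ``effect_size`` is the fold-of-control shift of a
    fully active endpoint at the top dose (1.0 = doubling over control);
    ``noise_sd`` is the well-level Gaussian noise SD in control units.
    """

    n_drugs: int = 122
    time_points_h: tuple[float, ...] = (1.0, 6.0, 24.0, 48.0)
    n_doses: int = 10
    max_dose_uM: float = 200.0
    dilution_factor: float = 2.0
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            CLASS_NECROSIS_EARLY: 15 / 45,
            CLASS_NECROSIS_LATE: 8 / 45,
            CLASS_NON_NECROSIS: 22 / 45,
        }
    )
    effect_size: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise ConfigurationError("n_drugs must be >= 1")
        if len(self.time_points_h) < 1 or list(self.time_points_h) != sorted(
            set(self.time_points_h)
        ):
            raise ConfigurationError("time_points_h must be increasing and distinct")
        if self.n_doses < 2:
            raise ConfigurationError("n_doses must be >= 2")
        if self.max_dose_uM <= 0:
            raise ConfigurationError("max_dose_uM must be positive")
        if self.dilution_factor <= 1:
            raise ConfigurationError("dilution_factor must be > 1")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_fractions must sum to 1 (got {total:.12f})"
            )
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigurationError("class_fractions must be non-negative")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def doses(self) -> np.ndarray:
        """Ascending dose grid: max_dose / f^(n-1), ..., max_dose."""
        steps = np.arange(self.n_doses - 1, -1, -1, dtype=float)
        return self.max_dose_uM / self.dilution_factor ** steps


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated curves plus planted ground truth."""

    curves: tuple[DoseResponseCurve, ...]           # treatments
    controls: tuple[DoseResponseCurve, ...]         # one per (endpoint, time)
    labels: Mapping[str, str]                       # drug -> class
    endpoint_groups: Mapping[str, int]              # endpoint -> event group
    schedule: Mapping[tuple[str, float], Mapping[int, float]]
    # (class, time) -> {group: activation multiplier}
    endpoints: tuple[EndpointSpec, ...]
    config: SimulationConfig


def default_schedule(
    classes: Sequence[str], time_points_h: Sequence[float]
) -> dict[tuple[str, float], dict[int, float]]:
    """Planted class x time activation schedule.

    Early-necrosis drugs drive group 1 at full strength from the first
    hour; late-necrosis drugs drive group 2 with strength ramping linearly
    over the time course; non-necrotic drugs drive group 3 mildly (0.4) at
    all times, emulating a regeneration-type response.
    """
    T = len(time_points_h)
    sched: dict[tuple[str, float], dict[int, float]] = {}
    for i, t in enumerate(time_points_h):
        sched[(CLASS_NECROSIS_EARLY, t)] = {1: 1.0}
        sched[(CLASS_NECROSIS_LATE, t)] = {2: (i + 1) / T}
        sched[(CLASS_NON_NECROSIS, t)] = {3: 0.4}
    return sched


def apportion(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n drugs over the class fractions."""
    names = list(fractions)
    quotas = np.array([fractions[c] * n for c in names])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # ties broken by catalog order (stable argsort on negated remainder)
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def _hill(dose: np.ndarray, ec50: float, slope: float = 1.5) -> np.ndarray:
    return 1.0 / (1.0 + (ec50 / dose) ** slope)


def generate_dataset(
    config: SimulationConfig,
    endpoints: Sequence[EndpointSpec] = DEFAULT_ENDPOINTS,
) -> SyntheticDataset:
    """Generate a complete synthetic dataset with planted structure.

    Every (drug, endpoint, time point) gets one treatment curve; every
    (endpoint, time point) gets one DMSO control curve on the same dose
    grid. With ``noise_sd=0`` and ``effect_size=0`` every treatment curve
    equals its control exactly. The same seed reproduces the dataset
    bit for bit.
    """
    if not endpoints:
        raise ConfigurationError("endpoint catalog must be non-empty")
    names = [e.name for e in endpoints]
    if len(set(names)) != len(names):
        raise ConfigurationError("endpoint names must be unique")

    rng = np.random.default_rng(config.seed)
    doses = config.doses
    times = config.time_points_h
    classes = list(config.class_fractions)
    schedule = default_schedule(classes, times)

    # deterministic label vector: apportion counts, then shuffle with the rng
    counts = apportion(config.class_fractions, config.n_drugs)
    label_vec = [c for c in classes for _ in range(counts[c])]
    label_vec = [label_vec[i] for i in rng.permutation(config.n_drugs)]
    width = len(str(config.n_drugs))
    drug_ids = [f"drug_{i + 1:0{width}d}" for i in range(config.n_drugs)]
    labels = dict(zip(drug_ids, label_vec))

    # per-drug potency: EC50 log-uniform over the central doses
    lo, hi = np.log2(doses[len(doses) // 4]), np.log2(doses[-2])
    ec50 = 2.0 ** rng.uniform(lo, hi, size=config.n_drugs)

    controls: list[DoseResponseCurve] = []
    for t in times:
        for spec in endpoints:
            values = 1.0 + rng.normal(0.0, config.noise_sd, size=len(doses))
            controls.append(
                DoseResponseCurve(CONTROL_DRUG_ID, spec.name, t, doses, values)
            )

    curves: list[DoseResponseCurve] = []
    for i, drug in enumerate(drug_ids):
        sig = _hill(doses, ec50[i])
        sig_top = sig[-1]
        for t in times:
            active = schedule.get((labels[drug], t), {})
            for spec in endpoints:
                mult = active.get(spec.event_group, 0.0)
                # scale so the mean top-dose shift equals effect_size * mult
                amp = config.effect_size * mult / sig_top if mult else 0.0
                values = 1.0 + amp * sig + rng.normal(
                    0.0, config.noise_sd, size=len(doses)
                )
                curves.append(DoseResponseCurve(drug, spec.name, t, doses, values))

    return SyntheticDataset(
        curves=tuple(curves),
        controls=tuple(controls),
        labels=labels,
        endpoint_groups={e.name: e.event_group for e in endpoints},
        schedule=schedule,
        endpoints=tuple(endpoints),
        config=config,
    )


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write curves.tsv, labels.tsv and truth.tsv into ``directory``.

    The truth table carries two row kinds, discriminated by the ``record``
    column: ``endpoint_group`` rows map endpoints to their planted event
    group; ``schedule`` rows list the active groups per (class, time).
    """
    if not dataset.curves:
        raise DataError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for curve in list(dataset.curves) + list(dataset.controls):
        is_ctrl = int(curve.drug_id == CONTROL_DRUG_ID)
        plate = next(
            (e.plate for e in dataset.endpoints if e.name == curve.endpoint_id), 1
        )
        for dose, value in zip(curve.doses, curve.values):
            rows.append(
                (curve.drug_id, curve.endpoint_id, plate, curve.time_h, dose, value, is_ctrl)
            )
    curves_df = pd.DataFrame(
        rows,
        columns=["drug_id", "endpoint_id", "plate", "time_h", "dose_uM", "value", "is_control"],
    )
    curves_path = directory / "curves.tsv"
    curves_df.to_csv(curves_path, sep="\t", index=False)

    labels_path = directory / "labels.tsv"
    pd.DataFrame(
        {"drug_id": list(dataset.labels), "class_label": list(dataset.labels.values())}
    ).to_csv(labels_path, sep="\t", index=False)

    truth_rows = [
        {"record": "endpoint_group", "endpoint_id": e, "event_group": g,
         "class_label": "", "time_h": "", "active_groups": ""}
        for e, g in dataset.endpoint_groups.items()
    ]
    for (cls, t), groups in dataset.schedule.items():
        truth_rows.append(
            {"record": "schedule", "endpoint_id": "", "event_group": "",
             "class_label": cls, "time_h": t,
             "active_groups": ";".join(f"{g}:{m}" for g, m in sorted(groups.items()))}
        )
    truth_path = directory / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    return {"curves": curves_path, "labels": labels_path, "truth": truth_path}


def read_truth_tsv(
    path: str | Path,
) -> tuple[dict[str, int], dict[tuple[str, float], dict[int, float]]]:
    """Read truth.tsv back into (endpoint -> group, schedule) maps."""
    df = pd.read_csv(path, sep="\t")
    if "record" not in df.columns:
        raise FileFormatError(f"{path}: missing 'record' column")
    groups: dict[str, int] = {}
    schedule: dict[tuple[str, float], dict[int, float]] = {}
    for _, row in df.iterrows():
        if row["record"] == "endpoint_group":
            groups[str(row["endpoint_id"])] = int(row["event_group"])
        elif row["record"] == "schedule":
            active = {}
            for item in str(row["active_groups"]).split(";"):
                g, _, m = item.partition(":")
                active[int(g)] = float(m) if m else 1.0
            schedule[(str(row["class_label"]), float(row["time_h"]))] = active
    return groups, schedule
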