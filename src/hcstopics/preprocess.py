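"""Dose-response curves to a discretized document-term corpus.

The transformation runs in four steps:

1. normalize each treatment dose-response curve by its matched vehicle
   (DMSO) control curve,
2. summarize each normalized curve as an area under the curve (AUC) over
   log2(dose), so that a no-effect curve scores exactly 0,
3. discretize each AUC-table column into ``n_bins`` equal-width bins,
   mapping every entry to a 1-based bin index, and
4. reorient the drug x (endpoint, time) table into a (drug, time) x
   endpoint count matrix — the corpus — where each drug-hour combination
   is a document and each endpoint is a word whose "occurrence count" is
   its bin index.

Documents are ordered drug-major then time ascending; terms follow the
endpoint catalog order. Both orders are deterministic so repeated runs
produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CompletenessError,
    DataError,
    DivisionError,
    FileFormatError,
)

CONTROL_DRUG_ID = "DMSO"

#: baseline of a no-effect normalized curve, per normalization mode
_BASELINES = {"ratio": 1.0, "difference": 0.0}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseCurve:
    """One endpoint's measurements across a dose series.

    Parameters
    ----------
    drug_id
        Treated compound identifier, or ``"DMSO"`` for a vehicle control.
    endpoint_id
        Cellular endpoint measured (e.g. ``"Steatosis"``).
    time_h
        Measurement time point in hours after treatment.
    doses
        Strictly increasing concentrations in uM; all positive because the
        AUC integrates over log2(dose).
    values
        Measurements aligned to ``doses``.
    """

    drug_id: str
    endpoint_id: str
    time_h: float
    doses: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "values", values)
        if doses.ndim != 1 or values.ndim != 1 or len(doses) != len(values):
            raise DataError(
                f"curve {self.drug_id}/{self.endpoint_id}@{self.time_h}h: "
                "doses and values must be 1-D and equally long"
            )
        if len(doses) < 2:
            raise DataError(
                f"curve {self.drug_id}/{self.endpoint_id}@{self.time_h}h: "
                "needs at least 2 dose points"
            )
        if np.any(doses <= 0):
            raise DataError(
                f"curve {self.drug_id}/{self.endpoint_id}@{self.time_h}h: "
                "doses must be positive (log-dose integration)"
            )
        if np.any(np.diff(doses) <= 0):
            raise DataError(
                f"curve {self.drug_id}/{self.endpoint_id}@{self.time_h}h: "
                "doses must be strictly increasing"
            )

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.drug_id, self.endpoint_id, self.time_h)


@dataclass(frozen=True)
class Corpus:
    """Document-term count matrix for topic modeling.

    Documents are drug-hour combinations; terms are endpoints. Counts are
    the 1-based bin indices of the discretized AUC table, so every term
    occurs at least once in every document and each row of ``counts`` has
    a positive total.
    """

    doc_ids: tuple[str, ...]          # "drug@time" labels
    doc_drugs: tuple[str, ...]
    doc_times: tuple[float, ...]
    term_ids: tuple[str, ...]
    counts: np.ndarray                # (n_docs, n_terms) non-negative int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            raise DataError("corpus counts must be integers")
        if counts.shape != (len(self.doc_ids), len(self.term_ids)):
            raise DataError("corpus counts shape does not match doc/term ids")
        if np.any(counts < 0):
            raise DataError("corpus counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    @property
    def total_tokens(self) -> int:
        return int(self.counts.sum())


def doc_label(drug_id: str, time_h: float) -> str:
    """Canonical ``drug@time`` document label (integral hours unpadded)."""
    t = int(time_h) if float(time_h).is_integer() else time_h
    return f"{drug_id}@{t}"


# ---------------------------------------------------------------------------
# normalization and AUC
# ---------------------------------------------------------------------------

def normalize_by_control(
    treatment: DoseResponseCurve,
    control: DoseResponseCurve,
    mode: str = "ratio",
) -> DoseResponseCurve:
    """Normalize a treatment curve by its matched DMSO control curve.

    ``mode="ratio"`` (fold-of-control, the HCS convention) divides
    pointwise; ``mode="difference"`` subtracts. Both curves must share
    the (endpoint, time) identity and an identical dose grid.
    """
    if mode not in _BASELINES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if (treatment.endpoint_id, treatment.time_h) != (control.endpoint_id, control.time_h):
        raise AlignmentError(
            f"treatment {treatment.endpoint_id}@{treatment.time_h}h and control "
            f"{control.endpoint_id}@{control.time_h}h are not the same assay"
        )
    if len(treatment.doses) != len(control.doses) or not np.array_equal(
        treatment.doses, control.doses
    ):
        raise AlignmentError(
            f"dose grids differ for {treatment.drug_id}/{treatment.endpoint_id}"
            f"@{treatment.time_h}h vs control"
        )
    if mode == "ratio":
        zero = np.flatnonzero(control.values == 0)
        if zero.size:
            raise DivisionError(
                f"control value is 0 at dose {control.doses[zero[0]]} uM "
                f"({control.endpoint_id}@{control.time_h}h)"
            )
        values = treatment.values / control.values
    else:
        values = treatment.values - control.values
    return dataclasses.replace(treatment, values=values)


def compute_auc(curve: DoseResponseCurve, baseline: float = 1.0) -> float:
    """Trapezoidal AUC of (value - baseline) over log2(dose).

    The dose series is a 2-fold dilution, so log2(dose) gives uniform
    spacing; integrating the deviation from the no-effect baseline makes
    a flat control-equal curve score 0 and the result invariant to the
    unit the doses are expressed in.
    """
    if len(curve.doses) < 2:  # unreachable through the constructor, kept for API
        raise DataError("AUC needs at least 2 dose points")
    return float(np.trapezoid(curve.values - baseline, np.log2(curve.doses)))


def build_auc_table(
    curves: Iterable[DoseResponseCurve],
    controls: Iterable[DoseResponseCurve],
    normalization: str = "ratio",
) -> pd.DataFrame:
    """Assemble the drug x (endpoint, time) AUC table.

    Column order is time-major then endpoint catalog order (order of first
    appearance in ``curves``); row order is drug order of first appearance.
    Every (drug, endpoint, time) combination must have a treatment curve
    and a matching control.

    Returns a DataFrame indexed by drug_id whose columns are a MultiIndex
    of (endpoint_id, time_h).
    """
    control_map: dict[tuple[str, float], DoseResponseCurve] = {}
    for c in controls:
        control_map[(c.endpoint_id, c.time_h)] = c

    drugs: list[str] = []
    endpoints: list[str] = []
    times: list[float] = []
    auc: dict[tuple[str, str, float], float] = {}
    baseline = _BASELINES[normalization] if normalization in _BASELINES else None
    if baseline is None:
        raise ValueError(f"unknown normalization mode {normalization!r}")

    for curve in curves:
        if curve.drug_id not in drugs:
            drugs.append(curve.drug_id)
        if curve.endpoint_id not in endpoints:
            endpoints.append(curve.endpoint_id)
        if curve.time_h not in times:
            times.append(curve.time_h)
        ctrl = control_map.get((curve.endpoint_id, curve.time_h))
        if ctrl is None:
            raise CompletenessError(
                f"no control curve for {curve.endpoint_id}@{curve.time_h}h"
            )
        normed = normalize_by_control(curve, ctrl, mode=normalization)
        auc[curve.key] = compute_auc(normed, baseline=baseline)

    times.sort()
    missing = [
        (d, e, t)
        for d in drugs
        for t in times
        for e in endpoints
        if (d, e, t) not in auc
    ]
    if missing:
        shown = ", ".join(f"{d}/{e}@{t}h" for d, e, t in missing[:5])
        more = f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""
        raise CompletenessError(f"missing treatment curves: {shown}{more}")

    columns = pd.MultiIndex.from_tuples(
        [(e, t) for t in times for e in endpoints], names=["endpoint_id", "time_h"]
    )
    data = np.array(
        [[auc[(d, e, t)] for (e, t) in columns] for d in drugs], dtype=float
    )
    return pd.DataFrame(data, index=pd.Index(drugs, name="drug_id"), columns=columns)


# ---------------------------------------------------------------------------
# discretization and corpus
# ---------------------------------------------------------------------------

def discretize(
    table: pd.DataFrame, n_bins: int = 100, scheme: str = "equal_width"
) -> pd.DataFrame:
    """Map each AUC-table column to 1-based integer bin indices.

    ``equal_width`` (default) splits [column min, column max] into
    ``n_bins`` equal bins; an entry's index is ``floor((v - min)/width) + 1``
    capped at ``n_bins``, so the column maximum maps to ``n_bins`` and a
    constant column maps entirely to 1. ``equal_frequency`` ranks the
    column and spreads ranks evenly over the bins instead.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scheme not in ("equal_width", "equal_frequency"):
        raise ValueError(f"unknown binning scheme {scheme!r}")
    values = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise DataError("AUC table contains non-finite entries")

    out = np.empty_like(values, dtype=np.int64)
    for j in range(values.shape[1]):
        col = values[:, j]
        if scheme == "equal_width":
            lo, hi = col.min(), col.max()
            if hi == lo:
                out[:, j] = 1
                continue
            width = (hi - lo) / n_bins
            idx = np.floor((col - lo) / width).astype(np.int64) + 1
            out[:, j] = np.minimum(idx, n_bins)
        else:
            # average ranks keep ties in the same bin
            from scipy.stats import rankdata

            rank = rankdata(col, method="average")
            idx = np.ceil(rank / len(col) * n_bins).astype(np.int64)
            out[:, j] = np.clip(idx, 1, n_bins)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def build_corpus(discrete_table: pd.DataFrame) -> Corpus:
    """Reorient the discretized drug x (endpoint, time) table into a corpus.

    Each (drug, time) pair becomes one document whose term counts are the
    bin indices of that drug's endpoints at that time. Document order is
    drug-major then time ascending; term order follows the table's
    endpoint catalog order.
    """
    if not isinstance(discrete_table.columns, pd.MultiIndex):
        raise DataError("expected a table with (endpoint_id, time_h) columns")
    values = discrete_table.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        raise DataError("table must be discretized to integers first")

    endpoints: list[str] = []
    times: list[float] = []
    for e, t in discrete_table.columns:
        if e not in endpoints:
            endpoints.append(e)
        if t not in times:
            times.append(t)
    times.sort()

    col_pos = {key: i for i, key in enumerate(discrete_table.columns)}
    drugs = list(discrete_table.index)
    doc_ids, doc_drugs, doc_times = [], [], []
    counts = np.empty((len(drugs) * len(times), len(endpoints)), dtype=np.int64)
    row = 0
    for i, d in enumerate(drugs):
        for t in times:
            doc_ids.append(doc_label(d, t))
            doc_drugs.append(d)
            doc_times.append(t)
            for j, e in enumerate(endpoints):
                counts[row, j] = values[i, col_pos[(e, t)]]
            row += 1
    return Corpus(
        doc_ids=tuple(doc_ids),
        doc_drugs=tuple(doc_drugs),
        doc_times=tuple(doc_times),
        term_ids=tuple(endpoints),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

CURVES_COLUMNS = ["drug_id", "endpoint_id", "plate", "time_h", "dose_uM", "value", "is_control"]


def read_curves_tsv(
    path: str | Path,
) -> tuple[list[DoseResponseCurve], list[DoseResponseCurve]]:
    """Read a curves TSV into (treatment curves, control curves).

    One row per dose level; curves are grouped by (drug, endpoint, time)
    and doses sorted ascending within each curve. Control rows carry
    ``is_control = 1`` and the drug_id ``DMSO``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CURVES_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    treatments: list[DoseResponseCurve] = []
    controls: list[DoseResponseCurve] = []
    grouped = df.groupby(["drug_id", "endpoint_id", "time_h", "is_control"], sort=False)
    for (drug, endpoint, time_h, is_ctrl), g in grouped:
        g = g.sort_values("dose_uM")
        curve = DoseResponseCurve(
            drug_id=str(drug),
            endpoint_id=str(endpoint),
            time_h=float(time_h),
            doses=g["dose_uM"].to_numpy(dtype=float),
            values=g["value"].to_numpy(dtype=float),
        )
        (controls if int(is_ctrl) else treatments).append(curve)
    return treatments, controls


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read the drug -> class label table (columns drug_id, class_label)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_id", "class_label"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    if df["drug_id"].duplicated().any():
        dupes = df.loc[df["drug_id"].duplicated(), "drug_id"].tolist()
        raise FileFormatError(f"{path}: duplicated drug_id {dupes[:5]}")
    return df.set_index("drug_id")["class_label"]


def _flat_columns(table: pd.DataFrame) -> list[str]:
    return [f"{e}@{int(t) if float(t).is_integer() else t}" for e, t in table.columns]


def write_auc_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the AUC (or discretized) table with endpoint@time columns."""
    out = table.copy()
    out.columns = _flat_columns(table)
    out.to_csv(path, sep="\t", index=True)


def read_auc_table_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pre-computed AUC table (drug_id, then endpoint@time columns)."""
    df = pd.read_csv(path, sep="\t", index_col="drug_id")
    tuples = []
    for col in df.columns:
        if "@" not in col:
            raise FileFormatError(f"{path}: column {col!r} is not endpoint@time")
        endpoint, _, t = col.rpartition("@")
        tuples.append((endpoint, float(t)))
    df.columns = pd.MultiIndex.from_tuples(tuples, names=["endpoint_id", "time_h"])
    return df


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the dense corpus TSV (doc_id + one integer column per term)."""
    df = pd.DataFrame(corpus.counts, columns=list(corpus.term_ids))
    df.insert(0, "doc_id", list(corpus.doc_ids))
    df.to_csv(path, sep="\t", index=False)


def read_corpus_tsv(path: str | Path) -> Corpus:
    df = pd.read_csv(path, sep="\t")
    if "doc_id" not in df.columns:
        raise FileFormatError(f"{path}: missing doc_id column")
    doc_ids = [str(x) for x in df["doc_id"]]
    drugs, times = [], []
    for d in doc_ids:
        drug, _, t = d.rpartition("@")
        drugs.append(drug)
        times.append(float(t))
    terms = [c for c in df.columns if c != "doc_id"]
    return Corpus(
        doc_ids=tuple(doc_ids),
        doc_drugs=tuple(drugs),
        doc_times=tuple(times),
        term_ids=tuple(terms),
        counts=df[terms].to_numpy(dtype=np.int64),
    )


def write_corpus_triplets(corpus: Corpus, path: str | Path) -> None:
    """Write a sparse triplet file: header ``n_docs n_terms nnz``, then
    1-based ``doc term count`` lines for every non-zero count."""
    rows, cols = np.nonzero(corpus.counts)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{corpus.n_docs}\t{corpus.n_terms}\t{len(rows)}\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i + 1}\t{j + 1}\t{corpus.counts[i, j]}\n")


def read_corpus_triplets(path: str | Path) -> Corpus:
    """Read the sparse triplet dialect; doc/term ids become positional."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 3:
            raise FileFormatError(f"{path}: bad header line")
        n_docs, n_terms, nnz = (int(x) for x in header)
        counts = np.zeros((n_docs, n_terms), dtype=np.int64)
        for line in fh:
            i, j, c = (int(x) for x in line.split())
            counts[i - 1, j - 1] = c
    doc_ids = tuple(f"doc_{i + 1}@0" for i in range(n_docs))
    return Corpus(
        doc_ids=doc_ids,
        doc_drugs=tuple(f"doc_{i + 1}" for i in range(n_docs)),
        doc_times=tuple(0.0 for _ in range(n_docs)),
        term_ids=tuple(f"term_{j + 1}" for j in range(n_terms)),
        counts=counts,
    )
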