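"""Diagnostic-topic statistics linking topics to histopathology classes.

For a partition of drugs into C classes and a fixed HCS time point, the
class mean of p(topic k | document) over the drugs of class c is mu_ck.
The significance score of topic k for class c normalizes the class
means over classes,

    S_ck = mu_ck / sum_c' mu_c'k ,

so each topic's scores sum to 1 across classes. The diagnostic topic of
class c is k* = argmax_k S_ck (ties resolved to the lowest topic index
and flagged, since near-0.5 scores in a two-class setting carry no
information).

Endpoints are assigned to topics the same way drugs are summarized:
each term goes to argmax_k p(term | topic k), splitting the vocabulary
into disjoint endpoint groups. The bridge report joins the two argmax
results — class -> diagnostic topic and topic -> endpoint set — into
the transitive in vitro -> topic -> in vivo linkage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, ConfigurationError, DataError
from .lda import TopicModel, rank_terms


@dataclass(frozen=True)
class ClassSetting:
    """A named partition of the evaluated drugs into classes.

    ``assignment`` maps every evaluated drug to exactly one of
    ``classes``; drugs absent from the assignment are simply not part of
    this setting's evaluation set.
    """

    name: str
    assignment: Mapping[str, str]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ConfigurationError(f"setting {self.name}: needs >= 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError(f"setting {self.name}: duplicate class names")
        unknown = set(self.assignment.values()) - set(self.classes)
        if unknown:
            raise ConfigurationError(
                f"setting {self.name}: labels {sorted(unknown)} not in classes"
            )
        for c in self.classes:
            if c not in set(self.assignment.values()):
                raise ConfigurationError(f"setting {self.name}: class {c!r} is empty")

    def drugs_in(self, cls: str) -> list[str]:
        return [d for d, c in self.assignment.items() if c == cls]


@dataclass(frozen=True)
class DiagnosticScoreMatrix:
    """Per-setting, per-time-point class x topic score matrix."""

    setting: ClassSetting
    time_h: float
    class_means: pd.DataFrame     # C x K, rows = classes
    scores: pd.DataFrame          # C x K, columns sum to 1 over classes
    diagnostic_topic: dict[str, int]   # class -> 1-based topic
    ties: dict[str, bool]


def make_settings(
    labels: Mapping[str, str],
    early_label: str = "necrosis_6h",
    late_label: str = "necrosis_24h",
) -> list[ClassSetting]:
    """Build the three standard binary settings from a 3-class label map.

    Setting I contrasts drugs necrotic at 6 h against all others;
    Setting II drugs necrotic at 24 h against all others; Setting III
    drugs necrotic at either time against drugs never necrotic.
    """
    def binary(name: str, pos: set[str]) -> ClassSetting:
        assignment = {
            d: ("necrosis" if lab in pos else "non_necrosis")
            for d, lab in labels.items()
        }
        return ClassSetting(name, assignment, ("necrosis", "non_necrosis"))

    return [
        binary("Setting I", {early_label}),
        binary("Setting II", {late_label}),
        binary("Setting III", {early_label, late_label}),
    ]


def class_means(
    doc_topic: pd.DataFrame,
    doc_index: Mapping[tuple[str, float], str],
    setting: ClassSetting,
    time_h: float | None,
) -> pd.DataFrame:
    """Within-class means mu_ck of p(topic|document) at one time point.

    ``doc_topic`` is indexed by doc_id with one column per topic;
    ``doc_index`` maps (drug, time) to the doc_id of that drug-hour
    document. Only the setting's drugs enter the means. With
    ``time_h=None`` a drug contributes all of its documents (pooled over
    time points) instead of the single one at ``time_h``.
    """
    rows = {}
    for cls in setting.classes:
        members = []
        for drug in setting.drugs_in(cls):
            if time_h is None:
                doc_ids = [i for (d, _), i in doc_index.items() if d == drug]
            else:
                hit = doc_index.get((drug, time_h))
                doc_ids = [] if hit is None else [hit]
            doc_ids = [i for i in doc_ids if i in doc_topic.index]
            if not doc_ids:
                raise CompletenessError(
                    f"drug {drug!r} has no document at "
                    f"{'any time point' if time_h is None else f'{time_h}h'}"
                )
            members.extend(doc_topic.loc[i] for i in doc_ids)
        rows[cls] = pd.concat(members, axis=1).mean(axis=1)
    mu = pd.DataFrame(rows).T.loc[list(setting.classes)]
    mu.index.name = "class"
    return mu


def diagnostic_scores(means: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize class means into S_ck = mu_ck / sum_c' mu_c'k."""
    mu = means.to_numpy(dtype=float)
    if np.any(mu < 0):
        raise DataError("class means must be non-negative")
    col_sums = mu.sum(axis=0)
    dead = np.flatnonzero(col_sums <= 0)
    if dead.size:
        cols = [means.columns[i] for i in dead]
        raise DataError(f"all-zero topic column(s): {cols}")
    return pd.DataFrame(mu / col_sums, index=means.index, columns=means.columns)


def diagnostic_topic(scores: pd.DataFrame) -> tuple[dict[str, int], dict[str, bool]]:
    """Per class, the topic with maximal score (1-based index).

    Exact ties go to the lowest topic index and are flagged.
    """
    out: dict[str, int] = {}
    ties: dict[str, bool] = {}
    values = scores.to_numpy(dtype=float)
    for i, cls in enumerate(scores.index):
        row = values[i]
        k = int(np.argmax(row))  # argmax returns the first (lowest) maximum
        out[str(cls)] = k + 1
        ties[str(cls)] = int((row == row[k]).sum()) > 1
    return out, ties


def compute_diagnostics(
    doc_topic: pd.DataFrame,
    doc_index: Mapping[tuple[str, float], str],
    setting: ClassSetting,
    time_points_h: Sequence[float],
) -> list[DiagnosticScoreMatrix]:
    """Score matrices for one setting at each HCS time point."""
    results = []
    for t in time_points_h:
        mu = class_means(doc_topic, doc_index, setting, t)
        s = diagnostic_scores(mu)
        topics, ties = diagnostic_topic(s)
        results.append(
            DiagnosticScoreMatrix(
                setting=setting, time_h=t, class_means=mu, scores=s,
                diagnostic_topic=topics, ties=ties,
            )
        )
    return results


def assign_endpoints(model: TopicModel) -> pd.DataFrame:
    """Assign each endpoint to its most probable topic.

    Returns a DataFrame with columns endpoint_id, topic (1-based), p and
    tie_flag; exact ties go to the lowest topic index and are flagged.
    """
    phi = model.topic_word
    rows = []
    for j, term in enumerate(model.term_ids):
        col = phi[:, j]
        k = int(np.argmax(col))
        rows.append(
            {"endpoint_id": term, "topic": k + 1, "p": float(col[k]),
             "tie_flag": int((col == col[k]).sum()) > 1}
        )
    return pd.DataFrame(rows)


def bridge_report(
    assignment: pd.DataFrame,
    diagnostics: Sequence[DiagnosticScoreMatrix],
    model: TopicModel,
) -> tuple[str, dict]:
    """Transitive linkage report: class -> diagnostic topic -> endpoints.

    Returns the Markdown text and an equivalent JSON-serializable dict
    with one section per (setting, time point).
    """
    topic_endpoints: dict[int, list[str]] = {}
    for _, row in assignment.iterrows():
        topic_endpoints.setdefault(int(row["topic"]), []).append(row["endpoint_id"])

    lines = ["# Bridge report: in vitro endpoints -> topics -> in vivo classes", ""]
    lines.append("## Endpoint assignment")
    lines.append("")
    for k in range(1, model.n_topics + 1):
        eps = topic_endpoints.get(k, [])
        lines.append(f"- Topic {k}: {', '.join(eps) if eps else '(no endpoints)'}")
    lines.append("")

    report: dict = {
        "endpoint_assignment": {
            str(k): topic_endpoints.get(k, []) for k in range(1, model.n_topics + 1)
        },
        "sections": [],
    }

    for diag in diagnostics:
        lines.append(f"## {diag.setting.name} — HCS time point {diag.time_h:g} h")
        lines.append("")
        section = {
            "setting": diag.setting.name,
            "time_h": diag.time_h,
            "scores": {
                str(cls): [float(x) for x in diag.scores.loc[cls]]
                for cls in diag.scores.index
            },
            "links": [],
        }
        for cls in diag.setting.classes:
            k = diag.diagnostic_topic[cls]
            tie = " (tie)" if diag.ties[cls] else ""
            eps = topic_endpoints.get(k, [])
            ranked = rank_terms(model, k)
            top = ", ".join(f"{t} ({p:.3f})" for t, p in ranked[:4])
            lines.append(
                f"- class **{cls}** -> diagnostic Topic {k}{tie} -> "
                f"endpoints {{{', '.join(eps)}}}; top terms: {top}"
            )
            section["links"].append(
                {"class": cls, "diagnostic_topic": k, "tie": diag.ties[cls],
                 "endpoints": eps,
                 "ranked_terms": [[t, float(p)] for t, p in ranked]}
            )
        lines.append("")
        report["sections"].append(section)

    return "\n".join(lines), report


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_scores(diagnostics: Sequence[DiagnosticScoreMatrix], path: str | Path) -> None:
    """scores TSV: rows time_h x class, topic columns, diagnostic_topic."""
    rows = []
    for diag in diagnostics:
        for cls in diag.scores.index:
            row = {"time_h": diag.time_h, "class": cls}
            for k, col in enumerate(diag.scores.columns, start=1):
                row[f"topic_{k}"] = diag.scores.loc[cls, col]
            row["diagnostic_topic"] = diag.diagnostic_topic[str(cls)]
            row["tie_flag"] = diag.ties[str(cls)]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_assignment(assignment: pd.DataFrame, path: str | Path) -> None:
    assignment.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_bridge_report(
    markdown: str, report: dict, md_path: str | Path, json_path: str | Path
) -> None:
    Path(md_path).write_text(markdown, encoding="utf-8")
    Path(json_path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
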