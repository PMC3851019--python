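"""End-to-end orchestration: simulate -> preprocess -> fit -> diagnose -> report.

A run is driven by one PipelineConfig (loadable from YAML/JSON). Each
stage derives its own seed deterministically from the global seed and
the stage name, so a stage can be re-run in isolation and the whole run
is reproducible: identical config and seed give byte-identical corpus,
CPT and score files. Every run writes a JSON manifest recording the
config, per-stage seeds and timings, and a SHA-256 checksum of every
output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, FileFormatError, HcsTopicsError
from . import preprocess as pp
from . import synthetic as syn
from .diagnostics import (
    assign_endpoints,
    bridge_report,
    compute_diagnostics,
    make_settings,
    write_assignment,
    write_bridge_report,
    write_scores,
)
from .lda import (
    LDAConfig,
    fit_lda,
    write_doc_topic,
    write_loglik_trace,
    write_model_json,
    write_topic_word,
)

logger = logging.getLogger("hcstopics")

STAGES = ("simulate", "preprocess", "fit", "diagnose", "report")


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: CRC-32 of "<seed>:<stage>", kept below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    output_dir: Path
    input_dir: Path | None = None          # required when simulate is False
    simulate: bool = True
    sim: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    normalization: str = "ratio"
    n_bins: int = 100
    binning: str = "equal_width"
    lda: LDAConfig = field(default_factory=LDAConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
            if self.input_dir.resolve() == self.output_dir.resolve():
                raise ConfigurationError("output_dir must differ from input_dir")
        if not self.simulate and self.input_dir is None:
            raise ConfigurationError("input_dir required when simulation is disabled")
        if self.normalization not in ("ratio", "difference"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.binning not in ("equal_width", "equal_frequency"):
            raise ConfigurationError(f"unknown binning {self.binning!r}")
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        # stage seeds flow from the global seed
        self.sim = dataclasses.replace(self.sim, seed=derive_seed(self.seed, "simulate"))
        self.lda = dataclasses.replace(self.lda, seed=derive_seed(self.seed, "fit"))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], Mapping):
            sim = dict(data["sim"])
            if "time_points_h" in sim:
                sim["time_points_h"] = tuple(float(t) for t in sim["time_points_h"])
            data["sim"] = syn.SimulationConfig(**sim)
        if "lda" in data and isinstance(data["lda"], Mapping):
            data["lda"] = LDAConfig(**data["lda"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        d["sim"]["time_points_h"] = list(self.sim.time_points_h)
        d["sim"]["class_fractions"] = dict(self.sim.class_fractions)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stage order: simulate (optional) -> preprocess -> fit -> diagnose ->
    report. Any stage failure is re-raised annotated with the stage name.
    The manifest is also written to ``output_dir/manifest.json``.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "stages": [],
        "outputs": {},
    }
    outputs: list[Path] = []

    def stage(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name: str, t0: float) -> None:
        manifest["stages"].append(
            {"name": name, "seconds": round(time.perf_counter() - t0, 4)}
        )
        logger.info("stage %s done", name)

    # --- simulate -----------------------------------------------------
    if config.simulate:
        t0 = stage("simulate")
        try:
            dataset = syn.generate_dataset(config.sim)
            paths = syn.write_dataset(dataset, out / "data")
        except HcsTopicsError as exc:
            raise type(exc)(f"[simulate] {exc}") from exc
        outputs.extend(paths.values())
        data_dir = out / "data"
        done("simulate", t0)
    else:
        data_dir = config.input_dir
        for fname in ("curves.tsv", "labels.tsv"):
            if not (data_dir / fname).is_file():
                raise FileFormatError(
                    f"[input] missing {data_dir / fname} and simulation is disabled"
                )

    # --- preprocess ---------------------------------------------------
    t0 = stage("preprocess")
    try:
        treatments, controls = pp.read_curves_tsv(data_dir / "curves.tsv")
        labels = pp.read_labels_tsv(data_dir / "labels.tsv")
        auc = pp.build_auc_table(treatments, controls, normalization=config.normalization)
        discrete = pp.discretize(auc, n_bins=config.n_bins, scheme=config.binning)
        corpus = pp.build_corpus(discrete)
        pp.write_auc_table(auc, out / "auc_table.tsv")
        pp.write_corpus(corpus, out / "corpus.tsv")
        pp.write_corpus_triplets(corpus, out / "corpus_triplets.tsv")
    except HcsTopicsError as exc:
        raise type(exc)(f"[preprocess] {exc}") from exc
    outputs += [out / "auc_table.tsv", out / "corpus.tsv", out / "corpus_triplets.tsv"]
    done("preprocess", t0)

    # --- fit ----------------------------------------------------------
    t0 = stage("fit")
    try:
        model = fit_lda(corpus, config.lda)
        write_doc_topic(model, out / "doc_topic.tsv")
        write_topic_word(model, out / "topic_word.tsv")
        write_loglik_trace(model, out / "loglik_trace.tsv")
        write_model_json(model, out / "model.json")
    except HcsTopicsError as exc:
        raise type(exc)(f"[fit] {exc}") from exc
    outputs += [out / "doc_topic.tsv", out / "topic_word.tsv",
                out / "loglik_trace.tsv", out / "model.json"]
    done("fit", t0)

    # --- diagnose -----------------------------------------------------
    t0 = stage("diagnose")
    try:
        doc_topic = pd.DataFrame(
            model.doc_topic,
            index=pd.Index(model.doc_ids, name="doc_id"),
            columns=[f"topic_{k + 1}" for k in range(model.n_topics)],
        )
        doc_index = {
            (drug, t): doc_id
            for doc_id, drug, t in zip(corpus.doc_ids, corpus.doc_drugs, corpus.doc_times)
        }
        times = sorted(set(corpus.doc_times))
        settings = make_settings(labels.to_dict())
        all_diags = {}
        for setting in settings:
            diags = compute_diagnostics(doc_topic, doc_index, setting, times)
            all_diags[setting.name] = diags
            fname = f"scores_{setting.name.replace(' ', '_')}.tsv"
            write_scores(diags, out / fname)
            outputs.append(out / fname)
        assignment = assign_endpoints(model)
        write_assignment(assignment, out / "assignment.tsv")
        outputs.append(out / "assignment.tsv")
    except HcsTopicsError as exc:
        raise type(exc)(f"[diagnose] {exc}") from exc
    done("diagnose", t0)

    # --- report -------------------------------------------------------
    t0 = stage("report")
    md, rep = bridge_report(
        assignment, [d for ds in all_diags.values() for d in ds], model
    )
    write_bridge_report(md, rep, out / "bridge_report.md", out / "bridge_report.json")
    outputs += [out / "bridge_report.md", out / "bridge_report.json"]
    done("report", t0)

    manifest["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: Sequence[str | Path]) -> dict[str, list[str]]:
    """Schema-check TSV inputs; returns {filename: [error, ...]}.

    Recognizes the curves and labels dialects by their columns. An empty
    error list for every file means the inputs are well-formed.
    """
    report: dict[str, list[str]] = {}
    for p in paths:
        p = Path(p)
        errors: list[str] = []
        report[str(p)] = errors
        if not p.is_file():
            errors.append("file not found")
            continue
        try:
            df = pd.read_csv(p, sep="\t")
        except Exception as exc:  # unreadable / not TSV
            errors.append(f"unreadable: {exc}")
            continue
        cols = set(df.columns)
        if {"drug_id", "class_label"} <= cols and "dose_uM" not in cols:
            dupes = df["drug_id"][df["drug_id"].duplicated()].tolist()
            if dupes:
                errors.append(f"duplicated drug_id: {dupes[:5]}")
            if df["class_label"].isna().any():
                errors.append("missing class_label values")
        elif set(pp.CURVES_COLUMNS) <= cols:
            if (df["dose_uM"] <= 0).any():
                errors.append("non-positive doses")
            for (drug, endpoint, t, _), g in df.groupby(
                ["drug_id", "endpoint_id", "time_h", "is_control"], sort=False
            ):
                doses = g["dose_uM"].to_numpy()
                if len(doses) < 2:
                    errors.append(f"{drug}/{endpoint}@{t}h: fewer than 2 doses")
                elif (pd.Series(doses).sort_values().diff().dropna() <= 0).any():
                    errors.append(f"{drug}/{endpoint}@{t}h: non-increasing doses")
            if not set(df["is_control"].unique()) <= {0, 1}:
                errors.append("is_control must be 0 or 1")
        else:
            errors.append(
                "unrecognized schema (expected curves or labels TSV columns)"
            )
    return report
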