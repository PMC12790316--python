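"""End-to-end screening workflow: SMILES in, affinity predictions out.

Stages, in order: parse + pattern check -> conformer search -> round-1
properties at the cheap level -> HOMO filter -> round-2 properties at
the refined level (survivors only) -> descriptor extraction -> MLR
prediction -> report.  The two-round economy is structural: the
expensive affinity-level calculations are never requested for
candidates the HOMO screen rejected.

Failures are sandboxed per nucleophile with a typed reject reason
(pattern, embedding, convergence, parse, missing-feature); one bad
input never aborts the batch.  All randomness derives from the single
config seed, and results are cached content-addressed, so rerunning an
identical config performs zero backend calls and reproduces the report
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .errors import (
    BackendError,
    Co2ScreenError,
    EmptyInputError,
    FeatureError,
    GeometryError,
    InputError,
    ParseError,
    PatternError,
    PipelineError,
)
from .descriptors import (
    DEFAULT_BURIED_RADIUS,
    DEFAULT_ANGULAR_STEP,
    build_descriptor_table,
)
from .modeling import (
    HOMO_THRESHOLD,
    MLRModel,
    Prediction,
    fit_mlr,
    homo_filter,
    predict,
)
from .qm_interface import (
    AFFINITY_PRESET,
    MockBackend,
    QMCache,
    QMSettings,
    run_backend,
    SCREENING_PRESET,
)
from .structures import (
    DEFAULT_ENERGY_WINDOW,
    DEFAULT_N_CONFS,
    DEFAULT_RMSD_THRESHOLD,
    Reject,
    embed_ensemble,
    parse_smiles_input,
    write_rejects,
)
from .units import ROOM_TEMPERATURE

__all__ = [
    "PipelineConfig",
    "ScreeningReport",
    "run_screening",
    "render_report",
    "derive_seed",
    "BACKENDS",
]

#: Registered backend factories, selectable by name in the config.
BACKENDS = {"mock": MockBackend}

#: Default model features: the three final-model descriptors under the
#: Boltzmann-weighted aggregation (the ensemble-aware default).
DEFAULT_MODEL_FEATURES = (
    "epsilon_homo_boltz",
    "site_dipole_boltz",
    "buried_b1_boltz",
)


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the single config seed (stable, < 2^31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Everything a screening run needs; serializable to/from YAML."""

    input: str = ""
    backend: str = "mock"
    model_path: str | None = None
    training_table: str | None = None
    model_features: tuple[str, ...] = DEFAULT_MODEL_FEATURES
    homo_threshold: float = HOMO_THRESHOLD  # Hartree
    temperature: float = ROOM_TEMPERATURE  # K
    n_confs: int = DEFAULT_N_CONFS
    energy_window: float = DEFAULT_ENERGY_WINDOW  # kcal/mol
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD  # Angstrom
    buried_radius: float = DEFAULT_BURIED_RADIUS  # Angstrom
    angular_step: float = DEFAULT_ANGULAR_STEP  # degrees
    homo_source: str = "lowE"  # which conformer feeds the round-1 filter
    screening_method: str = SCREENING_PRESET.method
    affinity_method: str = AFFINITY_PRESET.method
    solvent: str = "DMSO"
    output_dir: str = "runs/screen"
    cache_dir: str | None = None
    seed: int = 42

    def __post_init__(self):
        if not np.isfinite(self.homo_threshold):
            raise PipelineError("homo_threshold must be finite")
        if self.homo_source not in ("lowE", "boltz"):
            raise PipelineError("homo_source must be 'lowE' or 'boltz'")
        self.model_features = tuple(self.model_features)

    def settings(self, round_: int) -> QMSettings:
        method = self.screening_method if round_ == 1 else self.affinity_method
        return QMSettings(
            method=method,
            solvent=self.solvent,
            temperature=self.temperature,
            charge=-1,
            multiplicity=1,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ScreeningReport:
    """Outcome of one screening run.

    Every input id appears exactly once across predictions and rejects;
    the summary counts are derived from the rows, never tracked
    separately.
    """

    predictions: list[Prediction]
    rejects: list[Reject]
    descriptors: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def summary(self) -> dict:
        n_pass = sum(p.passed_homo_filter for p in self.predictions)
        return {
            "n_input": len(self.predictions) + len(self.rejects),
            "n_pattern_valid": len(self.predictions),
            "n_rejected": len(self.rejects),
            "n_passed_filter": n_pass,
            "n_predicted_stable": sum(
                p.stability_call == "stable" for p in self.predictions
            ),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": p.id,
                "epsilon_homo": p.epsilon_homo,
                "passed_homo_filter": p.passed_homo_filter,
                "co2a_pred": "" if p.co2a_pred is None else p.co2a_pred,
                "stability_call": p.stability_call,
            }
            for p in self.predictions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id",
                "epsilon_homo",
                "passed_homo_filter",
                "co2a_pred",
                "stability_call",
            ],
        )

    def hash(self) -> str:
        """Content hash of the result rows (reproducibility check)."""
        csv = self.to_frame().to_csv(index=False, float_format="%.10g")
        rej = "\n".join(f"{r.id}\t{r.reason}" for r in self.rejects)
        return hashlib.sha256((csv + rej).encode()).hexdigest()[:16]


def _resolve_model(config: PipelineConfig, model: MLRModel | None) -> MLRModel:
    if model is not None:
        return model
    if config.model_path:
        return MLRModel.load(config.model_path)
    if config.training_table:
        table = pd.read_csv(config.training_table, index_col="id")
        return fit_mlr(table, list(config.model_features))
    raise PipelineError(
        "no model available: supply model_path, training_table, or a model object"
    )


def run_screening(
    config: PipelineConfig,
    backend=None,
    model: MLRModel | None = None,
    cache: QMCache | None = None,
) -> ScreeningReport:
    """Execute the full screening workflow for one input file.

    ``backend``, ``model`` and ``cache`` may be injected (tests,
    embedding in larger workflows); otherwise they are constructed from
    the config.  Raises :class:`EmptyInputError` only when the input
    file has no lines at all; a file where every line is rejected
    yields an empty-but-valid report, flagged in the summary.
    """
    if backend is None:
        if config.backend not in BACKENDS:
            raise PipelineError(
                f"unknown backend {config.backend!r}; known: {sorted(BACKENDS)}"
            )
        backend = BACKENDS[config.backend]()
    mlr = _resolve_model(config, model)
    if cache is None:
        cache = QMCache(config.cache_dir)

    try:
        parsed = parse_smiles_input(config.input)
        records, rejects = parsed.records, list(parsed.rejects)
    except EmptyInputError:
        raise
    settings1 = config.settings(1)
    settings2 = config.settings(2)
    embed_seed = derive_seed(config.seed, "embed")

    predictions: list[Prediction] = []
    desc_frames: list[pd.DataFrame] = []
    for record in records:
        try:
            ensemble = embed_ensemble(
                record,
                n_confs=config.n_confs,
                seed=embed_seed,
                energy_window=config.energy_window,
                rmsd_threshold=config.rmsd_threshold,
            )
        except GeometryError as exc:
            rejects.append(Reject(record.id, -1, f"embedding: {exc}"))
            continue

        try:
            # round 1: cheap level, lowest-energy conformer (or the full
            # ensemble when the filter consumes the Boltzmann average)
            round1_confs = (
                ensemble.conformers if config.homo_source == "boltz" else ensemble.conformers[:1]
            )
            r1 = [
                run_backend(
                    c,
                    record.elements,
                    settings1,
                    backend,
                    cache=cache,
                    require=("single_point",),
                )
                for c in round1_confs
            ]
            if config.homo_source == "boltz":
                from .descriptors import boltzmann_weights

                w = boltzmann_weights(
                    [r.electronic_energy for r in r1], config.temperature
                )
                eps_homo = float(w @ np.array([r.homo_energy for r in r1]))
            else:
                eps_homo = r1[0].homo_energy
        except BackendError as exc:
            rejects.append(Reject(record.id, -1, f"convergence: {exc}"))
            continue
        except ParseError as exc:
            rejects.append(Reject(record.id, -1, f"parse: {exc}"))
            continue

        if not homo_filter(eps_homo, config.homo_threshold):
            predictions.append(
                Prediction(
                    id=record.id,
                    epsilon_homo=eps_homo,
                    passed_homo_filter=False,
                    co2a_pred=None,
                    stability_call="screened-out",
                )
            )
            continue

        try:
            # round 2: refined level, survivors only, full ensemble
            r2 = [
                run_backend(
                    c,
                    record.elements,
                    settings2,
                    backend,
                    cache=cache,
                    require=("single_point", "thermochemistry", "hirshfeld"),
                )
                for c in ensemble.conformers
            ]
            table = build_descriptor_table(
                [record],
                {record.id: ensemble},
                {record.id: r2},
                buried_radius=config.buried_radius,
                angular_step=config.angular_step,
                temperature=config.temperature,
            )
            row = table.complete.loc[record.id]
            predictions.append(
                predict(
                    mlr,
                    row,
                    record_id=record.id,
                    epsilon_homo=eps_homo,
                    threshold=config.homo_threshold,
                )
            )
            desc_frames.append(table.complete.loc[[record.id]])
        except BackendError as exc:
            rejects.append(Reject(record.id, -1, f"convergence: {exc}"))
        except FeatureError as exc:
            rejects.append(Reject(record.id, -1, f"missing-feature: {exc}"))
        except (KeyError, Co2ScreenError) as exc:
            rejects.append(Reject(record.id, -1, f"descriptor: {exc}"))

    descriptors = pd.concat(desc_frames) if desc_frames else None
    return ScreeningReport(
        predictions=predictions,
        rejects=rejects,
        descriptors=descriptors,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "embed_seed": embed_seed,
            "backend": getattr(backend, "name", str(backend)),
            "model_features": list(mlr.feature_names),
            "version": __version__,
        },
    )


def render_report(report: ScreeningReport, outdir: str | Path) -> list[Path]:
    """Write the results table, summary, rejects report and two plots.

    Plots: (i) ranking bar chart of predicted affinities, (ii)
    epsilon_HOMO vs site-dipole scatter with marker size encoding the
    buried B1 and color the predicted affinity.  Figures are SVG with
    no embedded timestamps, so identical reports render to identical
    bytes.
    """
    if report is None:
        raise PipelineError("cannot render a null report")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {outdir}: {exc}") from exc

    written: list[Path] = []
    results_path = outdir / "results.csv"
    report.to_frame().to_csv(results_path, index=False, float_format="%.10g")
    written.append(results_path)

    summary_path = outdir / "summary.json"
    summary_path.write_text(
        json.dumps(
            {"summary": report.summary, "provenance": report.provenance}, indent=2
        )
    )
    written.append(summary_path)

    rejects_path = outdir / "rejects.tsv"
    write_rejects(rejects_path, report.rejects)
    written.append(rejects_path)

    scored = [p for p in report.predictions if p.co2a_pred is not None]
    scored.sort(key=lambda p: p.co2a_pred, reverse=True)

    with plt.rc_context({"svg.hashsalt": "co2screen"}):
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(scored) + 2), 4))
        if scored:
            ids = [p.id for p in scored]
            vals = [p.co2a_pred for p in scored]
            colors = ["#2a7" if v > 0 else "#c44" for v in vals]
            ax.bar(range(len(ids)), vals, color=colors)
            ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=7)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("predicted CO$_2$ affinity / kcal mol$^{-1}$")
        ax.set_title("affinity ranking")
        fig.tight_layout()
        ranking_path = outdir / "ranking.svg"
        fig.savefig(ranking_path, metadata={"Date": None})
        plt.close(fig)
        written.append(ranking_path)

        fig, ax = plt.subplots(figsize=(5, 4))
        if report.descriptors is not None and len(report.descriptors):
            d = report.descriptors
            co2a = {p.id: p.co2a_pred for p in scored}
            vals = [co2a.get(i, np.nan) for i in d.index]
            sc = ax.scatter(
                d["epsilon_homo_boltz"],
                d["site_dipole_boltz"],
                s=80 * d["buried_b1_boltz"] / max(d["buried_b1_boltz"].max(), 1e-9),
                c=vals,
                cmap="coolwarm_r",
                edgecolors="k",
                linewidths=0.5,
            )
            fig.colorbar(sc, ax=ax, label="CO$_2$A / kcal mol$^{-1}$")
        ax.set_xlabel(r"$\varepsilon_\mathrm{HOMO}$ / $E_\mathrm{h}$")
        ax.set_ylabel("Hirshfeld site dipole / au")
        ax.set_title("descriptor map (size = buried B$_1$)")
        fig.tight_layout()
        scatter_path = outdir / "descriptors.svg"
        fig.savefig(scatter_path, metadata={"Date": None})
        plt.close(fig)
        written.append(scatter_path)

    return written
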