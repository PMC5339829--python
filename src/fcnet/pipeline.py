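"""End-to-end orchestration: simulate -> connect -> metrics -> stats -> classify.

A run is configured by :class:`RunConfig` (serializable to YAML/JSON),
executed stage by stage into an output directory, and stamped with a
provenance record (config, config hash, seeds, version, per-stage wall
time). Every stochastic step derives its seed deterministically from
``master_seed``, so identical configs reproduce every numeric output
exactly, regardless of stage composition order.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .connectivity import (
    ConnectivityMatrix,
    RoiTimeSeries,
    subject_connectivity,
    write_connectivity_tsv,
    read_connectivity_tsv,
)
from .metrics import metric_curves
from .mvpa import permutation_significance
from .network import SparsityGrid
from .stats import (
    PATIENT,
    auc_group_inference,
    edgewise_group_test,
    export_brainnet,
    spearman_clinical,
    write_edge_results_tsv,
    write_permutation_results_tsv,
)
from .synthetic import SyntheticConfig, simulate_cohort

#: Stage identifiers, also used as seed-derivation indices.
STAGES = ("simulate", "connect", "metrics", "stats", "classify")

CLINICAL_SCALES = ("lsas_total", "lsas_fear", "lsas_avoid", "hamd", "hama")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``manifest`` points at an existing cohort (CSV with the
    documented header) or ``synthetic`` holds a generator config — then
    the simulate stage writes the cohort under the output directory.
    """

    output_dir: str = "fcnet-run"
    manifest: str | None = None
    synthetic: SyntheticConfig | None = None
    s_min: float = 0.10
    s_max: float = 0.34
    s_step: float = 0.01
    n_null_networks: int = 100
    n_permutations_group: int = 10000
    n_permutations_classifier: int = 1000
    degree_log_base: str = "e"
    lp_disconnected: str = "exclude"
    freedman_lane: bool = False
    whole_sample_selection: bool = False
    select_alpha: float = 0.05
    classifier_features: tuple[str, ...] = ("aLp", "aCp")
    master_seed: int = 0

    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.s_step)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**dict(d["synthetic"]))
        if isinstance(d.get("classifier_features"), list):
            d["classifier_features"] = tuple(d["classifier_features"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def config_hash(self) -> str:
        # hash only analysis-relevant settings: the same analysis written
        # to two directories gets the same hash
        d = self.to_dict()
        d.pop("output_dir", None)
        if self.synthetic is not None:
            # the manifest is derived from the synthetic config (and its
            # resolved path depends on the output directory)
            d.pop("manifest", None)
        return hashlib.md5(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig, units: str) -> str:
    return (
        f"# fcnet {__version__} config={config.config_hash()} units={units}\n"
    )


def read_manifest(path: str | Path) -> tuple[pd.DataFrame, list[RoiTimeSeries]]:
    """Load and validate a cohort manifest plus all subject time series.

    The manifest is a CSV with columns ``subject_id, group, age, sex,
    <clinical scores>, timeseries_path`` (paths relative to the manifest
    directory). Raises named errors on missing columns, bad group
    labels, unreadable or NaN-containing series, and ROI-count
    mismatches across subjects.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group", "timeseries_path") if c not in table.columns]
    if missing:
        raise ValueError(f"manifest is missing required column(s): {missing}")
    labels = sorted(set(table["group"]))
    if set(labels) != {PATIENT, "control"}:
        raise ValueError(
            f"manifest group labels must be exactly {{'patient', 'control'}}, got {labels}"
        )
    series = []
    n_rois = None
    for _, row in table.iterrows():
        f = path.parent / row["timeseries_path"]
        if not f.exists():
            raise FileNotFoundError(f"time series for subject {row['subject_id']}: {f}")
        values = np.loadtxt(f, delimiter="\t", ndmin=2)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"NaN/Inf in time series of subject {row['subject_id']}")
        if n_rois is None:
            n_rois = values.shape[1]
        elif values.shape[1] != n_rois:
            raise ValueError(
                f"subject {row['subject_id']} has {values.shape[1]} ROIs, expected {n_rois}"
            )
        series.append(RoiTimeSeries(values=values))
    return table, series


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> Path:
    """Write the synthetic cohort and point the config's manifest at it."""
    if config.synthetic is None:
        raise ValueError("stage 'simulate' requires a synthetic config")
    out = Path(config.output_dir) / "cohort"
    simulate_cohort(config.synthetic, out)
    config.manifest = str(out / "manifest.csv")
    return out / "manifest.csv"


def stage_connect(config: RunConfig) -> Path:
    """Per-subject connectivity matrices (Pearson -> Fisher z -> positive)."""
    if config.manifest is None:
        default = Path(config.output_dir) / "cohort" / "manifest.csv"
        if not default.exists():
            raise ValueError("no manifest: run 'simulate' first or set one")
        config.manifest = str(default)
    table, series = read_manifest(config.manifest)
    out = Path(config.output_dir) / "connectivity"
    out.mkdir(parents=True, exist_ok=True)
    for sid, ts in zip(table["subject_id"], series):
        write_connectivity_tsv(subject_connectivity(ts), out / f"{sid}.tsv")
    table.to_csv(out / "subjects.csv", index=False)
    return out


def _load_connectivity(config: RunConfig) -> tuple[pd.DataFrame, list[ConnectivityMatrix]]:
    out = Path(config.output_dir) / "connectivity"
    if not (out / "subjects.csv").exists():
        raise ValueError("no connectivity outputs: run 'connect' first")
    table = pd.read_csv(out / "subjects.csv")
    mats = [read_connectivity_tsv(out / f"{sid}.tsv") for sid in table["subject_id"]]
    return table, mats


def stage_metrics(config: RunConfig) -> Path:
    """All metric curves and AUC summaries, plus the admissibility report."""
    table, mats = _load_connectivity(config)
    grid = config.grid()
    out = Path(config.output_dir) / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    long_rows, auc_rows, adm_rows = [], [], []
    for k, (sid, cm) in enumerate(zip(table["subject_id"], mats)):
        curves = metric_curves(
            cm,
            grid,
            n_null=config.n_null_networks,
            seed=np.random.SeedSequence([config.master_seed, STAGES.index("metrics"), k]),
            disconnected=config.lp_disconnected,
            degree_log_base=config.degree_log_base,
        )
        for m, vals in curves.global_values.items():
            for s, v in zip(grid.values, vals):
                long_rows.append((sid, s, m, "global", v))
        for m, vals in curves.nodal_values.items():
            for si, s in enumerate(grid.values):
                for node, v in enumerate(vals[si]):
                    long_rows.append((sid, s, m, cm.roi_labels[node], v))
        aucs = curves.auc()
        for key, v in aucs.items():
            if np.ndim(v) == 0:
                auc_rows.append((sid, key, "global", float(v)))
            else:
                for node, vv in enumerate(v):
                    auc_rows.append((sid, key, cm.roi_labels[node], float(vv)))
        for si, s in enumerate(grid.values):
            adm_rows.append(
                (
                    sid,
                    s,
                    curves.edge_counts[si],
                    curves.component_fraction[si],
                    bool(curves.admissible_degree[si]),
                    bool(curves.admissible_smallworld[si]),
                    curves.lp_excluded_pairs[si],
                )
            )
    hdr = _header(config, "dimensionless metric values per sparsity")
    with open(out / "metrics_long.tsv", "w") as fh:
        fh.write(hdr)
        pd.DataFrame(
            long_rows, columns=["subject_id", "sparsity", "metric", "node", "value"]
        ).to_csv(fh, sep="\t", index=False, float_format="%.10g")
    with open(out / "auc.tsv", "w") as fh:
        fh.write(_header(config, "metric x sparsity area (dimensionless)"))
        pd.DataFrame(auc_rows, columns=["subject_id", "metric", "node", "auc"]).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )
    with open(out / "admissibility.tsv", "w") as fh:
        fh.write(_header(config, "edge counts, fractions, booleans"))
        pd.DataFrame(
            adm_rows,
            columns=[
                "subject_id",
                "sparsity",
                "edge_count",
                "largest_component_fraction",
                "admissible_degree",
                "admissible_smallworld",
                "lp_excluded_pairs",
            ],
        ).to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return out


def _load_aucs(config: RunConfig) -> tuple[pd.DataFrame, list[dict], list[str]]:
    """Reassemble per-subject AUC dicts (and the subjects table)."""
    mdir = Path(config.output_dir) / "metrics"
    if not (mdir / "auc.tsv").exists():
        raise ValueError("no metric outputs: run 'metrics' first")
    table = pd.read_csv(Path(config.output_dir) / "connectivity" / "subjects.csv")
    auc = pd.read_csv(mdir / "auc.tsv", sep="\t", comment="#")
    roi_labels = [n for n in auc["node"].unique() if n != "global"]
    aucs = []
    for sid in table["subject_id"]:
        sub = auc[auc["subject_id"] == sid]
        d: dict = {}
        for metric, grp in sub.groupby("metric"):
            if (grp["node"] == "global").all():
                d[metric] = float(grp["auc"].iloc[0])
            else:
                byn = grp.set_index("node")["auc"]
                d[metric] = np.array([byn[n] for n in roi_labels])
        aucs.append(d)
    return table, aucs, roi_labels


def stage_stats(config: RunConfig) -> Path:
    """Edgewise tests, permutation AUC inference, clinical correlations."""
    table, mats = _load_connectivity(config)
    _, aucs, roi_labels = _load_aucs(config)
    groups = table["group"].to_numpy()
    covs = table[[c for c in ("age", "sex") if c in table.columns]]
    covariates = covs if len(covs.columns) else None
    out = Path(config.output_dir) / "stats"
    out.mkdir(parents=True, exist_ok=True)
    scheme = "freedman-lane" if config.freedman_lane else "simple"

    edges = edgewise_group_test(mats, groups)
    with open(out / "edge_tests.tsv", "w") as fh:
        fh.write(_header(config, "t statistics and probabilities on Fisher-z values"))
        write_edge_results_tsv(edges, fh)
    n_sig = export_brainnet(
        edges, mats[0].roi_labels, out / "significant.node", out / "significant.edge"
    )

    perm = auc_group_inference(
        aucs,
        groups,
        covariates=covariates,
        n_perm=config.n_permutations_group,
        seed=np.random.SeedSequence([config.master_seed, STAGES.index("stats"), 0]),
        scheme=scheme,
        roi_labels=roi_labels,
    )
    with open(out / "auc_group_tests.tsv", "w") as fh:
        fh.write(_header(config, "AUC differences (patient - control) and probabilities"))
        write_permutation_results_tsv(perm, fh)

    clin_rows = []
    pats = table["group"] == PATIENT
    scales = [c for c in CLINICAL_SCALES if c in table.columns]
    metrics_tested = [m for m in ("aLp", "aCp", "agamma", "asigma", "aEglob", "aEloc")
                      if m in aucs[0]]
    pairs = [(m, sc) for m in metrics_tested for sc in scales]
    for m, sc in pairs:
        vals = np.array([a[m] for a, keep in zip(aucs, pats) if keep])
        score = table.loc[pats, sc].to_numpy(dtype=float)
        try:
            rho, p = spearman_clinical(vals, score)
            p_bonf = min(1.0, p * len(pairs))
        except ValueError:
            rho, p, p_bonf = float("nan"), float("nan"), float("nan")
        clin_rows.append((m, sc, rho, p, p_bonf))
    with open(out / "clinical_correlations.tsv", "w") as fh:
        fh.write(_header(config, "Spearman rho and probabilities (patients only)"))
        pd.DataFrame(
            clin_rows, columns=["metric", "scale", "rho", "p", "p_bonferroni"]
        ).to_csv(fh, sep="\t", index=False, float_format="%.10g")

    summary = {
        "config_hash": config.config_hash(),
        "n_subjects": int(len(table)),
        "n_patients": int(pats.sum()),
        "n_edge_tests": int(len(edges)),
        "n_significant_edges_q05": int((edges["q"] < 0.05).sum()),
        "n_significant_edges_q01": int((edges["q"] < 0.01).sum()),
        "n_exported_edges": n_sig,
        "global_auc_tests": {
            r.metric_name: {"delta": r.observed_difference, "p": r.p_value}
            for r in perm
            if r.node == "global"
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out


def stage_classify(config: RunConfig) -> Path:
    """MLDA classification of individual subjects from AUC features."""
    table, aucs, _ = _load_aucs(config)
    groups = table["group"].to_numpy()
    feats = {}
    for name in config.classifier_features:
        if name not in aucs[0]:
            raise ValueError(f"classifier feature {name!r} not among computed AUCs")
        if np.ndim(aucs[0][name]) != 0:
            raise ValueError(f"classifier feature {name!r} is nodal; use global AUCs")
        feats[name] = np.array([a[name] for a in aucs])
    features = pd.DataFrame(feats)
    alpha = config.select_alpha
    fallback = False
    try:
        report = permutation_significance(
            features,
            groups,
            n_perm=config.n_permutations_classifier,
            seed=np.random.SeedSequence([config.master_seed, STAGES.index("classify"), 0]),
            nested_selection=not config.whole_sample_selection,
            alpha=alpha,
        )
    except ValueError:
        # no feature survives the screen (small or null cohorts): classify
        # on all candidate features and flag the fallback in the report
        fallback = True
        report = permutation_significance(
            features,
            groups,
            n_perm=config.n_permutations_classifier,
            seed=np.random.SeedSequence([config.master_seed, STAGES.index("classify"), 0]),
            nested_selection=not config.whole_sample_selection,
            alpha=1.0,
        )
    out = Path(config.output_dir) / "classification"
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": config.config_hash(),
        "selection_mode": report.selection_mode,
        "selection_alpha": 1.0 if fallback else alpha,
        "selection_fallback": fallback,
        "features": report.selected_features,
        "weights": report.weights.to_dict(orient="records"),
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "z_score": report.z_score,
        "permutation_p": report.permutation_p,
        "n_permutations": report.n_permutations,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    with open(out / "predictions.tsv", "w") as fh:
        fh.write(_header(config, "per-subject LOOCV predictions"))
        preds = report.predictions.copy()
        preds.insert(0, "subject_id", table["subject_id"])
        preds.drop(columns=["index"]).to_csv(fh, sep="\t", index=False)
    with open(out / "feature_values.tsv", "w") as fh:
        fh.write(_header(config, "per-subject feature values (AUC units)"))
        dump = features.copy()
        dump.insert(0, "subject_id", table["subject_id"])
        dump.insert(1, "group", groups)
        dump.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return out


def run_all(config: RunConfig) -> Path:
    """Execute all stages in order and write the provenance record."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "simulate": stage_simulate,
        "connect": stage_connect,
        "metrics": stage_metrics,
        "stats": stage_stats,
        "classify": stage_classify,
    }
    todo = [s for s in STAGES if s != "simulate" or config.synthetic is not None]
    walltime = {}
    for name in todo:
        t0 = time.perf_counter()
        try:
            stage_fns[name](config)
        except Exception as exc:  # noqa: BLE001 - annotate stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        walltime[name] = round(time.perf_counter() - t0, 3)
    provenance = {
        "fcnet_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stages": todo,
        "selection_scheme": "whole-sample" if config.whole_sample_selection else "nested",
        "wall_time_seconds": walltime,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return out
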