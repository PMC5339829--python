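"""Group inference: edgewise t-tests with FDR, covariate-adjusted
permutation tests on AUC metrics, and Spearman clinical correlations.

Edgewise comparison runs one pooled-variance two-sample t-test per unique
region pair on the Fisher-z connectivity values with Benjamini-Hochberg
FDR control across all pairs. Global and nodal AUC metrics are compared by
permutation: the statistic is the difference of group means of
covariate-adjusted (age, sex) values, the null is built by relabelling
subjects, and nodal results are FDR-corrected within each metric family.
Clinical associations in the patient group use Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix
from .metrics import GLOBAL_METRICS, NODAL_METRICS

#: Default group labels; the first is the positive/affected class.
PATIENT, CONTROL = "patient", "control"

#: Per-group sample size of the reference clinical summary table.
CLINICAL_TABLE_N = 42


# ---------------------------------------------------------------------------
# elementary tests


def two_sample_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-tailed.

    Returns (t, p) with ``len(x) + len(y) - 2`` degrees of freedom. The
    sign convention is mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.allclose(x.var(ddof=1) + y.var(ddof=1), 0.0):
        if np.isclose(x.mean(), y.mean()):
            # identical constant samples: no evidence of difference
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def two_sample_t_from_stats(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics (means, SDs, ns)."""
    if n_x < 2 or n_y < 2:
        raise ValueError("each sample needs at least 2 observations")
    if sd_x == 0 and sd_y == 0:
        if mean_x == mean_y:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind_from_stats(mean_x, sd_x, n_x, mean_y, sd_y, n_y, equal_var=True)
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, in [p, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def covariate_adjust(values, covariates) -> np.ndarray:
    """OLS residuals of per-subject values on intercept + covariates.

    ``covariates`` is an (n, k) array or DataFrame — typically age and
    sex coded 0/1. Columns constant across subjects are absorbed by the
    intercept, so the result degrades to mean-centred values; collinear
    covariates trigger a warning and a pseudo-inverse fit. ``values`` may
    be a vector or an (n, m) matrix (each column adjusted independently).
    """
    v = np.asarray(values, dtype=float)
    was_1d = v.ndim == 1
    if was_1d:
        v = v[:, None]
    x = _design_matrix(covariates, v.shape[0])
    beta = np.linalg.pinv(x) @ v
    resid = v - x @ beta
    return resid[:, 0] if was_1d else resid


def _design_matrix(covariates, n: int) -> np.ndarray:
    """Intercept + numeric covariate columns; sex-like strings coded 0/1."""
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        cols = [covariates[c].to_numpy() for c in covariates.columns]
    else:
        arr = np.asarray(covariates)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols = [arr[:, j] for j in range(arr.shape[1])]
    numeric = []
    for col in cols:
        if col.dtype.kind in "OUS":
            levels = sorted(set(col.tolist()))
            if len(levels) > 2:
                raise ValueError(f"categorical covariate has >2 levels: {levels}")
            numeric.append(np.asarray([levels.index(c) for c in col], dtype=float))
        else:
            numeric.append(np.asarray(col, dtype=float))
    x = np.column_stack([np.ones(n)] + numeric)
    if x.shape[0] != n:
        raise ValueError("covariates must have one row per subject")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn(
            "collinear covariates; using pseudo-inverse least squares", stacklevel=3
        )
    return x


# ---------------------------------------------------------------------------
# edgewise comparison


def edgewise_group_test(
    matrices: list[ConnectivityMatrix],
    groups,
    q_levels: tuple[float, ...] = (0.05, 0.01),
) -> pd.DataFrame:
    """One two-sample t-test per unique region pair on Fisher-z values.

    Returns a DataFrame with one row per unique off-diagonal pair
    (N(N-1)/2 tests) and columns i, j, i_label, j_label, t, p, q,
    direction (sign of patient - control mean) plus one boolean
    ``sig_q{level}`` column per requested FDR level. BH-FDR is applied
    across all pairs as one family.
    """
    groups = np.asarray(groups)
    labels = set(groups.tolist())
    if labels != {PATIENT, CONTROL}:
        raise ValueError(f"groups must be {{'patient', 'control'}}, got {sorted(labels)}")
    if len(matrices) != groups.size:
        raise ValueError("one connectivity matrix per subject required")
    n = matrices[0].n_rois
    z = np.stack([m.z_values for m in matrices])
    iu = np.triu_indices(n, 1)
    zp = z[groups == PATIENT][:, iu[0], iu[1]]
    zc = z[groups == CONTROL][:, iu[0], iu[1]]
    if zp.shape[0] < 2 or zc.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = sps.ttest_ind(zp, zc, axis=0, equal_var=True)
    # pairs identical across all subjects (e.g. clamped self-similar values)
    # have zero pooled variance; report t=0, p=1 for them
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    q = bh_fdr(p)
    roi = matrices[0].roi_labels
    out = pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "i_label": [roi[i] for i in iu[0]],
            "j_label": [roi[j] for j in iu[1]],
            "t": t,
            "p": p,
            "q": q,
            "direction": np.sign(zp.mean(axis=0) - zc.mean(axis=0)).astype(int),
        }
    )
    for level in q_levels:
        out[f"sig_q{level:g}"] = out["q"] < level
    return out


# ---------------------------------------------------------------------------
# permutation inference on AUC metrics


@dataclass
class PermutationResult:
    """Permutation test outcome for one metric (global or one node)."""

    metric_name: str
    node: str  # ROI label, or "global"
    observed_difference: float  # patient - control mean of adjusted values
    p_value: float
    q_value: float  # BH within the nodal family; equals p for global metrics
    n_permutations: int
    null_mean: float
    null_sd: float


def _permutation_deltas(
    values: np.ndarray,
    groups: np.ndarray,
    covariates,
    n_perm: int,
    rng: np.random.Generator,
    scheme: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted patient-minus-control mean differences.

    ``values`` is (n_subjects, n_metrics); returns (observed (m,),
    deltas (n_perm, m)). ``scheme='simple'`` residualizes once on the
    pooled sample and permutes group labels; ``scheme='freedman-lane'``
    permutes the reduced-model residuals, reconstructs pseudo-data and
    re-adjusts, keeping labels fixed.
    """
    n = values.shape[0]
    is_p = groups == PATIENT
    n1, n2 = int(is_p.sum()), int((~is_p).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    w = np.where(is_p, 1.0 / n1, -1.0 / n2)  # contrast: patient mean - control mean
    x = _design_matrix(covariates, n)
    hat = x @ np.linalg.pinv(x)
    resid = values - hat @ values
    observed = w @ resid
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    if scheme == "simple":
        # permuting labels == permuting the contrast weights
        weight_rows = w[perms]
        deltas = weight_rows @ resid
    elif scheme == "freedman-lane":
        # delta* = w.(I-H) resid[pi] = ((I-H)'w) . resid[pi]
        u = w - hat.T @ w
        weight_rows = u[np.argsort(perms, axis=1)]
        deltas = weight_rows @ resid
    else:
        raise ValueError(f"scheme must be 'simple' or 'freedman-lane', got {scheme!r}")
    return observed, deltas


def permutation_group_test(
    values,
    groups,
    covariates=None,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    scheme: str = "simple",
    metric_name: str = "metric",
    node: str = "global",
) -> PermutationResult:
    """Covariate-adjusted permutation test for a group difference.

    The statistic is the difference of group means (patient - control) of
    covariate-adjusted values; the null permutes group labels (group
    sizes preserved); two-tailed p uses the add-one estimator
    ``(1 + #{|delta_perm| >= |delta_obs|}) / (1 + n_perm)``, so
    p >= 1/(n_perm + 1) always.
    """
    values = np.asarray(values, dtype=float)[:, None]
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    observed, deltas = _permutation_deltas(values, groups, covariates, n_perm, rng, scheme)
    obs = float(observed[0])
    null = deltas[:, 0]
    p = float((1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1 + n_perm))
    return PermutationResult(
        metric_name=metric_name,
        node=node,
        observed_difference=obs,
        p_value=p,
        q_value=p,
        n_permutations=n_perm,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
    )


def auc_group_inference(
    aucs: list[dict],
    groups,
    covariates=None,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    scheme: str = "simple",
    roi_labels: list[str] | None = None,
) -> list[PermutationResult]:
    """Permutation tests over all AUC metrics of a cohort.

    ``aucs`` holds one dict per subject as returned by
    ``SubjectCurves.auc()`` (scalars keyed 'aCp', 'aLp', ... and arrays
    keyed 'anodalDeg', ...). All metrics share one permutation sequence
    (same relabellings), which preserves their dependence structure.
    Global metrics are reported without FDR (q = p); nodal metrics get
    BH-FDR across nodes within each metric family.
    """
    groups = np.asarray(groups)
    names: list[tuple[str, str]] = []  # (metric, node)
    cols: list[np.ndarray] = []
    first = aucs[0]
    glob = [f"a{m}" for m in GLOBAL_METRICS if f"a{m}" in first]
    nodal = [f"a{m}" for m in NODAL_METRICS if f"a{m}" in first]
    for key in glob:
        names.append((key, "global"))
        cols.append(np.array([float(a[key]) for a in aucs]))
    n_nodes = len(np.atleast_1d(first[nodal[0]])) if nodal else 0
    if roi_labels is None:
        roi_labels = [f"ROI{i + 1:03d}" for i in range(n_nodes)]
    for key in nodal:
        arr = np.stack([np.asarray(a[key], dtype=float) for a in aucs])
        for node in range(arr.shape[1]):
            names.append((key, roi_labels[node]))
            cols.append(arr[:, node])
    values = np.column_stack(cols)
    rng = np.random.default_rng(seed)
    observed, deltas = _permutation_deltas(values, groups, covariates, n_perm, rng, scheme)
    p = (1 + np.sum(np.abs(deltas) >= np.abs(observed)[None, :] - 1e-12, axis=0)) / (
        1 + n_perm
    )
    q = p.copy()
    for key in nodal:
        fam = np.array([k == key for k, _ in names])
        q[fam] = bh_fdr(p[fam])
    null_mean = deltas.mean(axis=0)
    null_sd = deltas.std(axis=0, ddof=1)
    return [
        PermutationResult(
            metric_name=names[k][0],
            node=names[k][1],
            observed_difference=float(observed[k]),
            p_value=float(p[k]),
            q_value=float(q[k]),
            n_permutations=n_perm,
            null_mean=float(null_mean[k]),
            null_sd=float(null_sd[k]),
        )
        for k in range(len(names))
    ]


# ---------------------------------------------------------------------------
# clinical correlations


def spearman_clinical(
    values, score, bonferroni_m: int | None = None
) -> tuple[float, float]:
    """Spearman rank correlation between a network metric and a clinical
    scale, computed on the patient group.

    Mid-rank ties; two-tailed p via the t approximation for n >= 10 and
    exact enumeration of rank permutations for n < 10. If
    ``bonferroni_m`` is given, p is multiplied by m (capped at 1),
    mirroring a Bonferroni correction across tested (metric, scale) pairs.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(score, dtype=float)
    if v.size != s.size:
        raise ValueError("values and score must have equal length")
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 patients")
    if np.all(v == v[0]) or np.all(s == s[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rv = sps.rankdata(v)
    rs = sps.rankdata(s)
    rho = float(np.corrcoef(rv, rs)[0, 1])
    if n >= 10:
        p = float(sps.spearmanr(v, s).pvalue)
    else:
        p = _spearman_exact_p(rv, rs, rho)
    if bonferroni_m is not None:
        p = min(1.0, p * bonferroni_m)
    return rho, p


def _spearman_exact_p(rv: np.ndarray, rs: np.ndarray, rho: float) -> float:
    """Two-tailed exact p by enumerating all n! rank pairings (n <= 9)."""
    n = rv.size
    perms = np.array(list(itertools.permutations(range(n))))
    a = rv - rv.mean()
    b = rs - rs.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    rho_all = (b[perms] @ a) / denom
    return float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))


# ---------------------------------------------------------------------------
# result output


def write_edge_results_tsv(results: pd.DataFrame, path) -> None:
    """Edge-test table as TSV (i_label, j_label, t, p, q, direction, ...)."""
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_permutation_results_tsv(results: list[PermutationResult], path) -> None:
    """Permutation-test table as TSV (metric, node, delta, p, q, null moments)."""
    pd.DataFrame(
        [
            {
                "metric": r.metric_name,
                "node": r.node,
                "delta": r.observed_difference,
                "p": r.p_value,
                "q": r.q_value,
                "n_permutations": r.n_permutations,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def export_brainnet(
    edge_results: pd.DataFrame,
    roi_labels: list[str],
    node_path,
    edge_path,
    q_level: float = 0.05,
    coords: np.ndarray | None = None,
) -> int:
    """Significant-edge export in BrainNet Viewer text formats.

    The .node file has one row per region: x y z color size label, where
    size is the region's number of altered (significant) connections and
    color flags regions with at least one. The .edge file is the full
    N x N matrix of t-values at significant pairs (0 elsewhere). Returns
    the number of significant edges.
    """
    n = len(roi_labels)
    if coords is None:
        # unit circle layout: placeholder coordinates when no atlas given
        theta = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta), np.zeros(n)])
    sig = edge_results[edge_results["q"] < q_level]
    mat = np.zeros((n, n))
    mat[sig["i"], sig["j"]] = sig["t"]
    mat[sig["j"], sig["i"]] = sig["t"]
    count = np.zeros(n, dtype=int)
    for idx in np.concatenate([sig["i"].to_numpy(), sig["j"].to_numpy()]):
        count[idx] += 1
    with open(node_path, "w") as fh:
        for k in range(n):
            fh.write(
                f"{coords[k, 0]:.3f}\t{coords[k, 1]:.3f}\t{coords[k, 2]:.3f}\t"
                f"{1 if count[k] else 0}\t{count[k]}\t{roi_labels[k]}\n"
            )
    np.savetxt(edge_path, mat, delimiter="\t", fmt="%.6g")
    return int(len(sig))
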