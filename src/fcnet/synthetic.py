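"""Synthetic two-group cohorts of ROI time series with known network topology.

The generator emulates the statistical endpoint of a resting-state fMRI
study — band-limited (0.01-0.1 Hz), correlated Gaussian regional time
series for two groups whose ground-truth coupling networks differ — so the
whole downstream pipeline (connectivity, thresholding, metrics, inference,
classification) can be exercised without any imaging data. It does not
model hemodynamics, head motion, or image acquisition.

Ground truth is a latent-factor correlation model on a ring of modules.
A mesh background grades between-module coupling by ring distance
(adjacent positive, distant negative), module factors create a dense
within-module tier that pins the sparsity-threshold cutoff well above
the cross-module noise, backbone cliques join adjacent modules, and
strong "spoke" pair factors couple offset-2 module pairs — the network's
long-range shortcuts and its strongest between-module couplings. The
"patient" group (a) attenuates the spokes, raising characteristic path
length, (b) loses a small within-module coupling component, so patient
modules retain fewer within-module edges under thresholding and the
clustering coefficient drops, and (c) gains promoted adjacent-module
pair couplings that replace the lost edge count (path-benign and
triangle-poor), so both groups fill the same sparsity budget and the
contrast reflects topology rather than raw connectivity strength. All
three levers scale with ``effect_size`` and vanish at zero effect.

Group-conditional clinical scores (LSAS total/fear/avoidance, HAMD, HAMA)
are drawn as truncated normals matching the study cohort's printed means
and SDs; by default they carry no relation to topology, unless
``clinical_link`` plants one via patient-specific effect jitter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .connectivity import RoiTimeSeries

#: Clinical score models: (patient mean, patient sd, control mean, control sd,
#: instrument minimum, instrument maximum). Values follow the study cohort's
#: demographics table (42 patients / 42 controls).
CLINICAL_MODELS = {
    "lsas_total": (69.40, 26.84, 20.29, 15.71, 0.0, 144.0),
    "lsas_fear": (34.12, 13.00, 9.79, 7.85, 0.0, 72.0),
    "lsas_avoid": (35.29, 15.05, 10.50, 9.52, 0.0, 72.0),
    "hamd": (12.60, 7.63, 2.17, 2.57, 0.0, 76.0),
    "hama": (14.14, 7.67, 1.79, 2.08, 0.0, 56.0),
}

#: Age models (mean, sd, low, high) per group, same source.
AGE_MODELS = {"patient": (27.33, 7.16, 18.0, 60.0), "control": (29.79, 8.78, 18.0, 60.0)}

#: Female fraction in both study groups (16 of 42).
FEMALE_FRACTION = 16 / 42

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "lsas_total",
    "lsas_fear",
    "lsas_avoid",
    "hamd",
    "hama",
    "timeseries_path",
]


#: Effect size at which the promoted (patient-gained) couplings reach their
#: configured value; promotion saturates beyond it so the variance budget
#: stays bounded for every effect size in [0, 1].
EFFECT_REFERENCE = 0.6


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Ground truth is a latent-factor correlation model (see
    :func:`make_ground_truth`): a ring-distance mesh background, a dense
    within-module tier, backbone cliques between adjacent modules, strong
    offset-2 "spoke" pairs (attenuated in patients), a small vulnerable
    within-module component (lost by patients), and promoted
    adjacent-module pairs (gained by patients). All couplings are stated
    as the *correlations they induce*; the model is positive
    semidefinite by construction, so planted values are realized exactly.

    The signal model: T x N white Gaussian draws are coloured by the
    Cholesky factor of the coupling matrix, band-pass filtered to
    ``(low_hz, high_hz)`` at the configured TR with a zero-phase
    Butterworth filter, and perturbed by white observation noise of
    standard deviation ``noise_sd``.
    """

    n_per_group: int = 42
    n_rois: int = 90
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    n_modules: int = 6
    mesh_coupling: float = 0.10
    within_coupling: float = 0.21
    within_vulnerable: float = 0.035
    backbone_coupling: float = 0.50
    spoke_coupling: float = 0.52
    n_spokes: int = 28
    promoted_coupling: float = 0.50
    n_promoted: int = 31
    spoke_exponent: int = 2
    within_exponent: int = 3
    effect_size: float = 0.0
    n_targeted_edges: int | None = None
    noise_sd: float = 0.2
    low_hz: float = 0.01
    high_hz: float = 0.1
    filter_order: int = 2
    clinical_link: float = 0.0
    effect_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be at least 3")
        if not (0.0 <= self.effect_size <= 1.0):
            raise ValueError("effect_size must lie in [0, 1]")
        if self.n_rois < 6:
            raise ValueError("need at least 6 ROIs")
        if self.n_modules < 4:
            raise ValueError("n_modules must be at least 4")
        if self.n_rois < 5 * self.n_modules:
            raise ValueError("need at least 5 ROIs per module")
        if not (0.0 <= self.clinical_link <= 1.0):
            raise ValueError("clinical_link must lie in [0, 1]")
        if self.n_targeted_edges is not None and self.n_targeted_edges > self.n_spokes:
            raise ValueError(
                f"n_targeted_edges={self.n_targeted_edges} exceeds the "
                f"{self.n_spokes} between-module spoke couplings"
            )
        # per-node variance budgets (worst cases: backbone node; spoke node
        # carrying a promoted pair, over all effect sizes in [0, 1])
        fixed = self.mesh_coupling + self.within_coupling
        backbone = fixed + self.within_vulnerable + self.backbone_coupling - self.mesh_coupling / 2
        prom = self.promoted_coupling - self.mesh_coupling / 2
        e = np.linspace(0.0, 1.0, 101)
        spoke_prom = (
            fixed
            + self.within_vulnerable * (1 - e) ** self.within_exponent
            + (self.spoke_coupling + self.mesh_coupling / 2) * (1 - e) ** self.spoke_exponent
            + prom * np.minimum(e / EFFECT_REFERENCE, 1.0)
        )
        if self.n_targeted_edges is not None and self.n_targeted_edges < self.n_spokes:
            if self.n_promoted > 0:
                # an unattenuated spoke node may also carry a promoted pair
                untargeted = (
                    fixed
                    + self.within_vulnerable * (1 - e) ** self.within_exponent
                    + (self.spoke_coupling + self.mesh_coupling / 2)
                    + prom * np.minimum(e / EFFECT_REFERENCE, 1.0)
                )
                spoke_prom = np.maximum(spoke_prom, untargeted)
        if backbone > 1.0 or float(spoke_prom.max()) > 1.0:
            raise ValueError(
                "per-node variance budget exceeded; reduce couplings "
                "(or set n_promoted=0 when targeting only part of the spokes)"
            )


@dataclass
class GroundTruth:
    """Planted coupling structure of the two groups.

    The factor construction yields exact correlation matrices (positive
    semidefinite, unit diagonal), so ``template_*`` and ``coupling_*``
    coincide; both are kept so downstream code can state which matrix it
    used. ``targeted_edges`` are the spoke pairs attenuated in group 2
    (patients); ``promoted_edges`` are the adjacent-module pairs whose
    coupling group 2 gains as the planted count-balancing redistribution.
    """

    template_group1: np.ndarray
    template_group2: np.ndarray
    coupling_group1: np.ndarray
    coupling_group2: np.ndarray
    targeted_edges: np.ndarray  # (k, 2) node pairs attenuated in group 2
    promoted_edges: np.ndarray  # (p, 2) node pairs strengthened in group 2
    modules: np.ndarray  # module index per node
    expected_direction: dict = field(
        default_factory=lambda: {"Lp": "group2 > group1", "Cp": "group2 < group1"}
    )


def _psd_clip(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal (deterministic)."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    w = np.maximum(w, floor)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    sizes = np.full(n_modules, n_rois // n_modules)
    sizes[: n_rois % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


def _topology(config: SyntheticConfig):
    """Deterministic layout of the planted structure.

    Returns a dict with the module assignment, the backbone-clique node
    sets, the spoke pairs (offset-2 module pairs, one node each, walking
    through within-module positions), and the promoted adjacent-module
    pairs (degree at most one per node, allocated from the high
    positions downward so nodes without spokes are used first).
    """
    n, n_mod = config.n_rois, config.n_modules
    modules = _module_assignment(n, n_mod)
    members = [np.flatnonzero(modules == m) for m in range(n_mod)]
    sizes = [len(mem) for mem in members]

    backbone = []
    for m in range(n_mod):
        m2 = (m + 1) % n_mod
        backbone.append(
            [int(members[m][2]), int(members[m][3]), int(members[m2][0]), int(members[m2][1])]
        )

    offset = 2 if n_mod >= 5 else n_mod // 2
    far_pairs = [(m, (m + offset) % n_mod) for m in range(n_mod)]
    nxt = [4] * n_mod
    spokes = []
    k = 0
    while len(spokes) < config.n_spokes and k < 40 * len(far_pairs):
        ma, mb = far_pairs[k % len(far_pairs)]
        k += 1
        if nxt[ma] >= sizes[ma] or nxt[mb] >= sizes[mb]:
            continue
        spokes.append((int(members[ma][nxt[ma]]), int(members[mb][nxt[mb]])))
        nxt[ma] += 1
        nxt[mb] += 1
    if len(spokes) < config.n_spokes:
        raise ValueError(
            f"n_spokes={config.n_spokes} exceeds the available offset-{offset} node pairs"
        )

    used = np.zeros(n, dtype=bool)
    promoted = []
    adj_pairs = [(m, (m + 1) % n_mod) for m in range(n_mod)]
    k = 0
    while len(promoted) < config.n_promoted and k < 60 * len(adj_pairs):
        ma, mb = adj_pairs[k % len(adj_pairs)]
        k += 1
        i = j = None
        for q in range(sizes[ma] - 1, 3, -1):
            if not used[members[ma][q]]:
                i = int(members[ma][q])
                break
        for q in range(sizes[mb] - 1, 3, -1):
            if not used[members[mb][q]] and int(members[mb][q]) != i:
                j = int(members[mb][q])
                break
        if i is None or j is None:
            break
        used[[i, j]] = True
        promoted.append((i, j))
    if len(promoted) < config.n_promoted:
        raise ValueError(
            f"n_promoted={config.n_promoted} exceeds the available adjacent-module node pairs"
        )
    return {"modules": modules, "backbone": backbone, "spokes": spokes, "promoted": promoted}


def _coupling_for_effect(
    config: SyntheticConfig, topo: dict, effect: float
) -> np.ndarray:
    """Exact correlation matrix at a given attenuation level.

    ``effect = 0`` yields the control template; the group-2 template uses
    ``effect = config.effect_size``. Positive semidefinite by
    construction (sum of rank-one factor covariances plus a non-negative
    diagonal), so no repair step is needed.
    """
    n = config.n_rois
    modules = topo["modules"]
    hb = config.mesh_coupling
    theta = 2.0 * np.pi * modules / config.n_modules
    cols = [np.sqrt(hb) * np.cos(theta), np.sqrt(hb) * np.sin(theta)]
    spoke_scale = np.sqrt((1.0 - effect) ** config.spoke_exponent)
    vulnerable_scale = np.sqrt((1.0 - effect) ** config.within_exponent)
    promoted_scale = np.sqrt(min(effect / EFFECT_REFERENCE, 1.0))
    for m in range(config.n_modules):
        lam = np.zeros(n)
        lam[modules == m] = np.sqrt(config.within_coupling)
        cols.append(lam)
        lam = np.zeros(n)
        lam[modules == m] = np.sqrt(config.within_vulnerable) * vulnerable_scale
        cols.append(lam)
    for nodes in topo["backbone"]:
        lam = np.zeros(n)
        lam[nodes] = np.sqrt(config.backbone_coupling - hb / 2)
        cols.append(lam)
    k_att = (
        len(topo["spokes"])
        if config.n_targeted_edges is None
        else config.n_targeted_edges
    )
    for idx, (i, j) in enumerate(topo["spokes"]):
        lam = np.zeros(n)
        lam[[i, j]] = np.sqrt(config.spoke_coupling + hb / 2) * (
            spoke_scale if idx < k_att else 1.0
        )
        cols.append(lam)
    for i, j in topo["promoted"]:
        lam = np.zeros(n)
        lam[[i, j]] = np.sqrt(config.promoted_coupling - hb / 2) * promoted_scale
        cols.append(lam)
    lam_mat = np.stack(cols, axis=1)
    shared = lam_mat @ lam_mat.T
    resid = 1.0 - np.diag(shared)
    if resid.min() < -1e-9:
        raise ValueError("per-node variance budget exceeded; reduce couplings")
    sigma = shared + np.diag(np.maximum(resid, 0.0))
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return sigma


def make_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Build the two groups' coupling (correlation) matrices.

    Group 1 realizes the full factor model. Group 2 attenuates the spoke
    factors (the strongest between-module couplings) by ``effect_size``
    with exponent ``spoke_exponent``, removes the vulnerable
    within-module component with exponent ``within_exponent``, and gains
    the promoted adjacent-module couplings (scaled by ``effect_size``
    relative to ``EFFECT_REFERENCE``, saturating above it). With
    ``n_targeted_edges`` set, only that many spokes (in construction
    order) are attenuated. The layout is deterministic: identical
    configs yield identical matrices.
    """
    topo = _topology(config)
    sigma1 = _coupling_for_effect(config, topo, 0.0)
    sigma2 = _coupling_for_effect(config, topo, config.effect_size)
    k = len(topo["spokes"]) if config.n_targeted_edges is None else config.n_targeted_edges
    targeted = np.array(topo["spokes"][:k], dtype=int).reshape(k, 2)
    n_prom = len(topo["promoted"])
    promoted = np.array(topo["promoted"], dtype=int).reshape(n_prom, 2)
    return GroundTruth(
        template_group1=sigma1,
        template_group2=sigma2,
        coupling_group1=sigma1,
        coupling_group2=sigma2,
        targeted_edges=targeted,
        promoted_edges=promoted,
        modules=topo["modules"],
    )


def bandpass_filter(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 2,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass per column; the mean is removed.

    ``low_hz`` may be 0, in which case a pure low-pass is applied. The band
    must lie strictly below the Nyquist frequency 1/(2 TR).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist} Hz "
            "(require 0 <= low < high < Nyquist)"
        )
    x = ts.values - ts.values.mean(axis=0)
    if low_hz > 0:
        sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    else:
        sos = butter(order, high_hz, btype="lowpass", fs=1.0 / ts.tr_seconds, output="sos")
    y = sosfiltfilt(sos, x, axis=0)
    y = y - y.mean(axis=0)
    out = object.__new__(RoiTimeSeries)  # bypass the non-constant-column check:
    out.values = np.asarray(y, float)  # a filtered constant column is all zeros
    out.tr_seconds = ts.tr_seconds
    out.roi_labels = ts.roi_labels
    return out


def regress_nuisance(ts: RoiTimeSeries, regressors: np.ndarray) -> RoiTimeSeries:
    """Least-squares residuals of every column on the regressor span."""
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != ts.n_timepoints:
        raise ValueError("regressors must have one row per time point")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        import warnings

        warnings.warn("rank-deficient nuisance regressors; using pseudo-inverse", stacklevel=2)
    beta = np.linalg.pinv(x) @ ts.values
    resid = ts.values - x @ beta
    out = object.__new__(RoiTimeSeries)
    out.values = resid
    out.tr_seconds = ts.tr_seconds
    out.roi_labels = ts.roi_labels
    return out


def simulate_subject(
    coupling: np.ndarray,
    config: SyntheticConfig,
    subject_seed: int | np.random.SeedSequence,
) -> RoiTimeSeries:
    """One subject's T x N series with the given target coupling.

    White Gaussian draws are coloured by the Cholesky factor of the
    coupling matrix (zero-lag cross-correlation equals the coupling in
    expectation, and identical per-column filtering preserves it), then
    band-pass filtered and perturbed by white observation noise.
    """
    coupling = np.asarray(coupling, dtype=float)
    wmin = float(np.linalg.eigvalsh(coupling).min())
    if wmin < -1e-8:
        raise ValueError(f"coupling matrix is not positive semidefinite (min eig {wmin:.3g})")
    rng = np.random.default_rng(subject_seed)
    n = coupling.shape[0]
    chol = np.linalg.cholesky(coupling + 1e-10 * np.eye(n))
    white = rng.standard_normal((config.n_timepoints, n))
    raw = RoiTimeSeries(
        values=white @ chol.T,
        tr_seconds=config.tr_seconds,
        roi_labels=[f"ROI{i + 1:03d}" for i in range(n)] if n != 90 else None,
    )
    filtered = bandpass_filter(raw, config.low_hz, config.high_hz, config.filter_order)
    values = filtered.values + config.noise_sd * rng.standard_normal(filtered.values.shape)
    return RoiTimeSeries(values=values, tr_seconds=config.tr_seconds, roi_labels=raw.roi_labels)


def _truncated_normal(rng, mean, sd, low, high, size):
    """Draw-until-accept truncated normal (ranges are wide; cheap)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def simulate_cohort(config: SyntheticConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write one time-series TSV per subject plus a manifest CSV.

    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``). Time-series files are headerless TSVs of T
    rows x N columns; the manifest stores paths relative to its own
    directory. Output is a pure function of the config (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = make_ground_truth(config)
    topo = _topology(config)  # for subject-specific attenuation levels
    root = np.random.SeedSequence([config.seed, 1])
    demo_rng = np.random.default_rng(root.spawn(1)[0])

    rows = []
    n = config.n_per_group
    for g_idx, group in enumerate(["patient", "control"]):
        mean_age, sd_age, lo_age, hi_age = AGE_MODELS[group]
        ages = _truncated_normal(demo_rng, mean_age, sd_age, lo_age, hi_age, n)
        n_female = int(round(FEMALE_FRACTION * n))
        sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
        demo_rng.shuffle(sexes)
        # latent severity index per subject drives the planted
        # clinical-topology link (if any)
        latent = demo_rng.standard_normal(n)
        clin = {}
        for name, (pm, ps, cm_, cs, lo, hi) in CLINICAL_MODELS.items():
            mean, sd = (pm, ps) if group == "patient" else (cm_, cs)
            indep = _truncated_normal(demo_rng, 0.0, 1.0, (lo - mean) / sd, (hi - mean) / sd, n)
            zmix = config.clinical_link * latent + np.sqrt(1 - config.clinical_link**2) * indep
            clin[name] = np.clip(mean + sd * zmix, lo, hi)
        for i in range(n):
            sid = f"sub-{group[:3]}{i + 1:03d}"
            subject_seed = np.random.SeedSequence([config.seed, 2, g_idx, i])
            if group == "patient" and (config.effect_jitter > 0 or config.clinical_link > 0):
                # subject-specific attenuation tied to the latent severity
                eff = float(
                    np.clip(
                        config.effect_size * (1.0 + config.effect_jitter * latent[i]),
                        0.0,
                        1.0,
                    )
                )
                coupling = _coupling_for_effect(config, topo, eff)
            else:
                coupling = gt.coupling_group1 if group == "control" else gt.coupling_group2
            ts = simulate_subject(coupling, config, subject_seed)
            fname = f"{sid}.tsv"
            np.savetxt(out_dir / fname, ts.values, delimiter="\t", fmt="%.10g")
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": round(float(ages[i]), 1),
                    "sex": sexes[i],
                    **{k: round(float(v[i]), 1) for k, v in clin.items()},
                    "timeseries_path": fname,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def manifest_checksum(path: str | Path) -> str:
    """MD5 of a manifest file, for reproducibility checks."""
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
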