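"""Self-contained validation experiments.

Each function builds its own small synthetic problem, runs the package's
implementation on it, and returns the measured quantity together with the
reference the implementation is expected to match (an independent oracle, a
planted parameter, or an analytic expectation).  They back the pipeline's
``verify`` stage and the repository's acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph

from . import behavior as bh
from .cluster import dbscan_clusters
from .epochs import EpochSet
from .fdr import fdr_bh
from .headmodel import build_grid, fibonacci_sensors, spherical_leadfield
from .source_dics import csd, dics_filters, neural_activity_index
from .source_lcmv import ClusterTimeSeries
from .synthdata import coupled_modulators
from .xcorr import fdr_threshold, timewise_correlation

__all__ = [
    "dics_localization",
    "xcorr_recovery",
    "null_calibration",
    "bh_stepup_bruteforce",
    "bh_oracle_check",
    "dbscan_oracle_check",
    "anova_balanced_oracle",
    "anova_oracle_check",
]


def dics_localization(
    n_seeds: int = 100,
    snr: float = 10.0,
    seed: int = 0,
    n_channels: int = 32,
    grid_radius: float = 0.06,
    spacing: float = 0.012,
    n_trials: int = 30,
    freq: float = 10.0,
    lam: float = 0.05,
) -> dict:
    """Single-dipole localization accuracy of the DICS stage.

    Each replicate plants one oscillating dipole at a random grid voxel,
    forward-models ``n_trials`` one-second trials at amplitude signal-to-noise
    ``snr`` (sensor RMS ratio), and asks whether the argmax of the
    unit-noise-gain (NAI) source map falls within one grid step of the truth.
    Returns the success fraction.
    """
    rng = np.random.default_rng(seed)
    sensors = fibonacci_sensors(n_channels, radius=0.09)
    grid = build_grid(grid_radius, spacing)
    lf = spherical_leadfield(grid, sensors)
    sfreq = 256.0
    n_samp = int(sfreq)
    times = np.arange(n_samp) / sfreq
    band = (freq - 2.0, freq + 2.0)
    hits = 0
    for _ in range(n_seeds):
        vox = int(rng.integers(grid.n_voxels))
        ori = rng.standard_normal(3)
        ori /= np.linalg.norm(ori)
        gain = lf.gain[:, vox, :] @ ori
        sig_rms = np.sqrt(np.mean(gain**2)) / np.sqrt(2.0)
        noise_sd = sig_rms / snr
        data = rng.normal(0.0, noise_sd, size=(n_trials, n_channels, n_samp))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
        osc = np.sin(2.0 * np.pi * freq * times[None, :] + phases[:, None])
        data += gain[None, :, None] * osc[:, None, :]
        ep = EpochSet(
            data, sfreq, 0.0, sensors.names, np.array(["other"] * n_trials)
        )
        c = csd(ep, band, (0.0, 1000.0))
        filt = dics_filters(c, lf, lam=lam)
        nai = neural_activity_index(filt, c)
        best = int(np.argmax(nai.values))
        dist = np.linalg.norm(grid.positions[best] - grid.positions[vox])
        hits += dist <= spacing * 1.0001
    return {"success_rate": hits / n_seeds, "n_seeds": n_seeds}


def xcorr_recovery(
    n_participants: int = 200,
    rho: float = 0.7,
    seed: int = 0,
    n_times: int = 16,
    cv: float = 0.25,
    noise_sd: float = 0.02,
) -> dict:
    """Recovery of a planted pre/post power coupling by the correlation stage.

    Participant-level pre- and post-trial cluster power modulators are drawn
    with correlation ``rho``; the time-resolved correlation matrix should
    show a mean r inside the 95% Fisher confidence interval around ``rho``.
    """
    rng = np.random.default_rng(seed)
    mods = coupled_modulators(n_participants, rho, cv, rng)
    pre_p = mods[:, [0]] + rng.normal(0.0, noise_sd * cv, (n_participants, n_times))
    post_p = mods[:, [1]] + rng.normal(0.0, noise_sd * cv, (n_participants, n_times))
    pre = ClusterTimeSeries(pre_p, np.linspace(-2500, -1500, n_times), (4, 7), (-2500, -1500))
    post = ClusterTimeSeries(post_p, np.linspace(0, 1000, n_times), (4, 7), (0, 1000))
    corr = timewise_correlation(pre, post)
    mean_r = float(np.nanmean(corr.r))
    zc = np.arctanh(rho)
    half = 1.96 / np.sqrt(n_participants - 3)
    lo, hi = np.tanh(zc - half), np.tanh(zc + half)
    return {
        "mean_r": mean_r,
        "target_rho": rho,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "in_ci": bool(lo <= mean_r <= hi),
        "n": n_participants,
    }


def null_calibration(
    n_replicates: int = 200,
    n_participants: int = 30,
    n_pre: int = 12,
    n_post: int = 12,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive calibration of the correlation stage under the null.

    Independent Gaussian pre and post series should give ~alpha raw
    positives per matrix, and the BH-masked family-level discovery rate
    (probability of any q < alpha cell under the global null) should not
    exceed alpha by more than sampling error.
    """
    rng = np.random.default_rng(seed)
    raw_rates = np.empty(n_replicates)
    any_fdr = np.empty(n_replicates, dtype=bool)
    pre_t = np.linspace(-2500, -1500, n_pre)
    post_t = np.linspace(0, 1000, n_post)
    for i in range(n_replicates):
        pre = ClusterTimeSeries(
            rng.standard_normal((n_participants, n_pre)), pre_t, (4, 7), (-2500, -1500)
        )
        post = ClusterTimeSeries(
            rng.standard_normal((n_participants, n_post)), post_t, (4, 7), (0, 1000)
        )
        corr = timewise_correlation(pre, post)
        raw_rates[i] = np.mean(corr.p < alpha)
        any_fdr[i] = fdr_threshold(corr, alpha).any()
    return {
        "raw_false_positive_rate": float(raw_rates.mean()),
        "fdr_family_discovery_rate": float(any_fdr.mean()),
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up adjusted p-values: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def bh_oracle_check(n_vectors: int = 1000, seed: int = 0, max_len: int = 40) -> dict:
    """Agreement of the package BH adjustment with the step-up definition."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
        max_diff = max(max_diff, float(np.abs(fdr_bh(p) - bh_stepup_bruteforce(p)).max()))
    return {"max_abs_diff": max_diff, "n_vectors": n_vectors}


def _eps_graph_partition(points: np.ndarray, eps: float):
    """Connected components of the eps-neighborhood graph; singletons = noise."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    adj = scipy.sparse.csr_matrix((d <= eps) & ~np.eye(len(points), dtype=bool))
    _, comp = scipy.sparse.csgraph.connected_components(adj, directed=False)
    clusters, noise = [], set()
    for cid in np.unique(comp):
        members = np.where(comp == cid)[0]
        if members.size == 1:
            noise.add(int(members[0]))
        else:
            clusters.append(frozenset(int(i) for i in members))
    return frozenset(clusters), frozenset(noise)


def dbscan_oracle_check(n_sets: int = 50, seed: int = 0, n_points: int = 80, eps: float = 0.15) -> dict:
    """DBSCAN (minPts=2) vs brute-force eps-graph connected components."""
    from .headmodel import SourceGrid

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sets):
        pts = rng.uniform(size=(n_points, 3))
        grid = SourceGrid(pts, spacing=eps / 1.5)
        cs = dbscan_clusters(np.arange(n_points), grid, eps=eps)
        got_clusters = frozenset(
            frozenset(int(v) for v in cs.members(cid)) for cid in cs.cluster_ids
        )
        got_noise = frozenset(int(v) for v in cs.voxel_indices[cs.labels == -1])
        want_clusters, want_noise = _eps_graph_partition(pts, eps)
        agree += got_clusters == want_clusters and got_noise == want_noise
    return {"agreement_rate": agree / n_sets, "n_sets": n_sets}


def anova_balanced_oracle(y: np.ndarray, group: np.ndarray) -> dict:
    """Brute-force classical SS decomposition for the balanced mixed design.

    ``y`` has shape (n_subjects, 2, 2) indexed (response, feature) and the
    two groups must have equal size (the oracle's balanced case).  Marginal
    means are computed explicitly; error strata by subtraction.
    """
    g_ids = np.unique(group)
    assert len(g_ids) == 2
    n_per = [np.sum(group == g) for g in g_ids]
    assert n_per[0] == n_per[1], "oracle requires equal group sizes"
    n_subj = y.shape[0]
    gm = y.mean()
    m_g = {g: y[group == g].mean() for g in g_ids}
    m_r = y.mean(axis=(0, 2))
    m_f = y.mean(axis=(0, 1))
    m_rf = y.mean(axis=0)
    m_s = y.mean(axis=(1, 2))
    m_gr = {g: y[group == g].mean(axis=(0, 2)) for g in g_ids}
    m_gf = {g: y[group == g].mean(axis=(0, 1)) for g in g_ids}
    m_grf = {g: y[group == g].mean(axis=0) for g in g_ids}
    m_sr = y.mean(axis=2)
    m_sf = y.mean(axis=1)

    ss = {}
    ss["group"] = 4 * sum(n * (m_g[g] - gm) ** 2 for g, n in zip(g_ids, n_per))
    ss["response"] = 2 * n_subj * np.sum((m_r - gm) ** 2)
    ss["feature"] = 2 * n_subj * np.sum((m_f - gm) ** 2)
    ss["response:feature"] = n_subj * np.sum(
        (m_rf - m_r[:, None] - m_f[None, :] + gm) ** 2
    )
    ss["response:group"] = 2 * sum(
        n * np.sum((m_gr[g] - m_g[g] - m_r + gm) ** 2) for g, n in zip(g_ids, n_per)
    )
    ss["feature:group"] = 2 * sum(
        n * np.sum((m_gf[g] - m_g[g] - m_f + gm) ** 2) for g, n in zip(g_ids, n_per)
    )
    ss["response:feature:group"] = sum(
        n
        * np.sum(
            (
                m_grf[g]
                - m_gr[g][:, None]
                - m_gf[g][None, :]
                - m_rf
                + m_g[g]
                + m_r[:, None]
                + m_f[None, :]
                - gm
            )
            ** 2
        )
        for g, n in zip(g_ids, n_per)
    )
    m_gs = np.array([m_g[g] for g in group])
    ss["error_between"] = 4 * np.sum((m_s - m_gs) ** 2)
    total_r = 2 * np.sum((m_sr - m_s[:, None]) ** 2)
    ss["error_response"] = total_r - ss["response"] - ss["response:group"]
    total_f = 2 * np.sum((m_sf - m_s[:, None]) ** 2)
    ss["error_feature"] = total_f - ss["feature"] - ss["feature:group"]
    total_rf = np.sum((y - m_sr[:, :, None] - m_sf[:, None, :] + m_s[:, None, None]) ** 2)
    ss["error_response:feature"] = (
        total_rf - ss["response:feature"] - ss["response:feature:group"]
    )
    return {k: float(v) for k, v in ss.items()}


def anova_oracle_check(seed: int = 0, n_per_group: int = 6) -> dict:
    """Implementation-vs-oracle SS agreement on a random balanced dataset."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    y = rng.normal(size=(n, 2, 2)) + rng.normal(size=(n, 1, 1))
    group = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    table = pd.DataFrame(
        {
            "participant": [f"s{i}" for i in range(n)],
            "group": group,
            "RRFR": y[:, 0, 0],
            "RRFA": y[:, 0, 1],
            "RAFR": y[:, 1, 0],
            "RAFA": y[:, 1, 1],
        }
    )
    got = bh.mixed_anova_2x2x2(table)
    want = anova_balanced_oracle(y, group)
    diffs = []
    for _, row in got.iterrows():
        diffs.append(abs(row["ss"] - want[row["effect"]]))
    err_map = {
        "group": "error_between",
        "response": "error_response",
        "feature": "error_feature",
        "response:feature": "error_response:feature",
    }
    for effect, err_key in err_map.items():
        got_err = got.loc[got["effect"] == effect, "ss_error"].iloc[0]
        diffs.append(abs(got_err - want[err_key]))
    return {"max_abs_ss_diff": float(max(diffs))}
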