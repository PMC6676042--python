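"""Patient- and group-level statistics.

Per patient: Spearman correlation between distance-to-lesion and
concordance (per gradient), anatomical-distance residualisation, slope and
intercept of the distance–concordance regression. Per group: one-tailed
Wilcoxon signed-rank tests, lesion-size control, gradient-bin
delta-concordance with permutation testing, and Kendall tau associations
with clinical scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class BinAnalysis:
    """Delta-concordance between lesion-unaffected and -affected gradient bins."""

    n_bins: int
    affected_bins: np.ndarray
    mu_unaffected: float
    mu_affected: float
    delta_concordance: float = field(init=False)

    def __post_init__(self):
        self.delta_concordance = self.mu_unaffected - self.mu_affected


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def spearman_distance_concordance(dist, conc, min_voxels: int = 10) -> float:
    """Spearman rank correlation of distance-to-lesion vs concordance.

    Ties receive average ranks. A positive value means concordance rises
    with distance — connectivity change over time is concentrated in
    voxels functionally close to the lesion.
    """
    d, c = _clean_pair(dist, conc)
    if d.size < min_voxels:
        raise ValueError(f"only {d.size} usable voxels, need >= {min_voxels}")
    r, _ = stats.spearmanr(d, c)
    return float(r)


def wilcoxon_signed_rank(values, alternative: str = "greater") -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of median > 0 (or < 0 / != 0).

    Zeros are dropped; ties in |value| get average ranks. For n <= 25 the
    p-value comes from the exact null distribution of the positive rank
    sum (dynamic programme over doubled midranks, so tied midranks stay
    exact); above that, a normal approximation with tie-corrected variance
    and continuity correction. Returns (W, p) with W = min(T+, T-).
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    if n == 0:
        raise ValueError("all values are zero")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero values, got {n}")
    ranks = stats.rankdata(np.abs(v))
    t_plus = float(ranks[v > 0].sum())
    t_minus = float(ranks[v < 0].sum())
    w = min(t_plus, t_minus)

    if n <= 25:
        # exact null: distribution of 2*T+ over all 2^n sign assignments
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] = counts[r:] + counts[: total + 1 - r]
        counts /= 2.0**n
        obs2 = int(round(2 * t_plus))
        p_ge = float(counts[obs2:].sum())
        p_le = float(counts[: obs2 + 1].sum())
    else:
        mu = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_sizes**3 - tie_sizes).sum()) / 48.0
        sd = np.sqrt(var)
        p_ge = float(stats.norm.sf((t_plus - 0.5 - mu) / sd))
        p_le = float(stats.norm.cdf((t_plus + 0.5 - mu) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w, min(p, 1.0)


def residualize_anatomy(conc, anat):
    """Remove the linear anatomical-distance component from concordance.

    Ordinary least squares of concordance on anatomical distance (with
    intercept). Returns (anat_r, residuals): the Pearson correlation of
    the two maps, and the residual map (NaN where either input was NaN)
    for re-correlation with gradient distance.
    """
    conc = np.asarray(conc, dtype=float)
    anat = np.asarray(anat, dtype=float)
    ok = ~(np.isnan(conc) | np.isnan(anat))
    a, c = anat[ok], conc[ok]
    if a.size < 3:
        raise ValueError("too few voxels for residualisation")
    if np.ptp(a) == 0:
        raise ValueError("anatomical distance has zero variance")
    anat_r = float(stats.pearsonr(a, c)[0])
    slope, intercept = np.polyfit(a, c, 1)
    resid = np.full_like(conc, np.nan)
    resid[ok] = c - (slope * a + intercept)
    return anat_r, resid


def fit_slope_intercept(dist, conc) -> tuple[float, float]:
    """OLS of concordance on distance-to-lesion; returns (slope, intercept)."""
    d, c = _clean_pair(dist, conc)
    if d.size < 3:
        raise ValueError("too few voxels for regression")
    if np.ptp(d) == 0:
        raise ValueError("distance map has zero variance")
    slope, intercept = np.polyfit(d, c, 1)
    return float(slope), float(intercept)


def lesion_size_control(volumes, rs_values) -> tuple[float, float]:
    """Pearson correlation between lesion volume and per-patient r_s."""
    v = np.asarray(volumes, dtype=float)
    r = np.asarray(rs_values, dtype=float)
    if v.size < 5:
        raise ValueError("need >= 5 patients")
    if np.ptp(v) == 0:
        raise ValueError("lesion volumes are constant")
    if np.ptp(r) == 0:
        raise ValueError("per-patient correlations are constant")
    rho, p = stats.pearsonr(v, r)
    return float(rho), float(p)


def bin_delta_concordance(grad_values, lesion_grad_values, conc, n_bins: int) -> BinAnalysis:
    """Delta-concordance over a uniform binning of one gradient.

    The gradient range [min, max] (over intact and lesioned voxels
    together) is split into ``n_bins`` equal bins, left-closed with a
    right-closed final bin. Bins holding at least one lesioned voxel are
    "lesion-affected". The statistic is the mean concordance of intact
    voxels in unaffected bins minus that in affected bins (lesioned voxels
    never enter either mean); positive values mean preferential change in
    the affected part of the gradient.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    g = np.asarray(grad_values, dtype=float)
    gl = np.asarray(lesion_grad_values, dtype=float)
    c = np.asarray(conc, dtype=float)
    lo = min(g.min(), gl.min())
    hi = max(g.max(), gl.max())
    edges = np.linspace(lo, hi, n_bins + 1)

    def assign(x):
        return np.clip(np.digitize(x, edges, right=False) - 1, 0, n_bins - 1)

    affected = np.unique(assign(gl))
    vox_bins = assign(g)
    ok = ~np.isnan(c)
    in_affected = np.isin(vox_bins, affected)
    aff_vals = c[ok & in_affected]
    unaff_vals = c[ok & ~in_affected]
    if unaff_vals.size == 0:
        raise ValueError("every occupied bin is lesion-affected")
    mu_aff = float(aff_vals.mean()) if aff_vals.size else float("nan")
    mu_unaff = float(unaff_vals.mean())
    return BinAnalysis(
        n_bins=n_bins,
        affected_bins=affected,
        mu_unaffected=mu_unaff,
        mu_affected=mu_aff,
    )


def permutation_group_diff(
    values,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> float:
    """Permutation test for a difference in group means.

    The statistic is mean(group A) - mean(group B), where A is the first
    of the two labels in sorted order (so the direction does not depend on
    input ordering). Monte Carlo p-values use the add-one estimator
    (1 + #extreme) / (n_perm + 1); ``exact=True`` enumerates all
    label assignments instead (feasible for small groups).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size != 2:
        raise ValueError("labels must contain exactly two groups")
    is_a = lab == uniq[0]
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = v.size

    def stat(mask_a):
        return v[mask_a].mean() - v[~mask_a].mean()

    obs = stat(is_a)

    def extreme(s):
        if alternative == "greater":
            return s >= obs
        if alternative == "less":
            return s <= obs
        if alternative == "two-sided":
            return np.abs(s) >= abs(obs)
        raise ValueError(f"unknown alternative {alternative!r}")

    if exact:
        n_tot = comb(n, n_a)
        count = 0
        for idx in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if extreme(stat(mask)):
                count += 1
        return count / n_tot

    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    order = np.argsort(keys, axis=1)
    a_idx = order[:, :n_a]
    # draw from the sorted values: the permutation null only depends on the
    # multiset of values, so this makes p invariant to input ordering
    v_sorted = np.sort(v)
    total = v_sorted.sum()
    sums_a = v_sorted[a_idx].sum(axis=1)
    perms = sums_a / n_a - (total - sums_a) / n_b
    return float((1 + int(extreme(perms).sum())) / (n_perm + 1))


def kendall_clinical(values, scores) -> tuple[float, float]:
    """Kendall tau-b between a per-patient measure and an ordinal score."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(scores, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(s))
    v, s = v[ok], s[ok]
    if v.size < 5:
        raise ValueError("need >= 5 patients")
    if np.ptp(s) == 0:
        raise ValueError("all clinical scores are tied")
    tau, p = stats.kendalltau(v, s)
    return float(tau), float(p)


def run_group_analysis(patient_results, clinical=None, n_perm: int = 10000, seed: int = 0) -> dict:
    """Assemble the full group-level report from per-patient results.

    ``patient_results`` is a list of dicts, one per patient, with keys
    ``patient_id``, ``r_s``, ``r_s_residualized``, ``slope``,
    ``intercept`` (each a length-K list), ``anat_r``,
    ``lesion_volume_cm3``, and optionally ``delta_concordance`` mapping
    str(n_bins) -> length-K list. ``clinical`` is a DataFrame indexed like
    the patients with columns nihss_day0/nihss_day5/mrs_day0/mrs_day5.

    Returns a JSON-serialisable dict, deterministic for a fixed seed.
    Clinical blocks are skipped (with a logged warning) when scores are
    missing or one clinical-change group is empty.
    """
    if len(patient_results) < 5:
        raise ValueError("need >= 5 patients with complete results")
    K = len(patient_results[0]["r_s"])
    rs = np.array([p["r_s"] for p in patient_results])
    rs_res = np.array([p["r_s_residualized"] for p in patient_results])
    slopes = np.array([p["slope"] for p in patient_results])
    intercepts = np.array([p["intercept"] for p in patient_results])
    anat_r = np.array([p["anat_r"] for p in patient_results])
    volumes = np.array([p["lesion_volume_cm3"] for p in patient_results])

    report: dict = {
        "n_patients": len(patient_results),
        "n_gradients": K,
        "patient_ids": [p["patient_id"] for p in patient_results],
        "gradients": {},
        "anatomical_control": {},
        "bin_analysis": {},
        "clinical_association": {},
        "warnings": [],
    }

    for k in range(K):
        w, p = wilcoxon_signed_rank(rs[:, k], alternative="greater")
        w_res, p_res = wilcoxon_signed_rank(rs_res[:, k], alternative="greater")
        try:
            size_r, size_p = lesion_size_control(volumes, rs[:, k])
        except ValueError as e:
            size_r, size_p = None, None
            report["warnings"].append(f"gradient {k + 1} lesion-size control skipped: {e}")
        report["gradients"][str(k + 1)] = {
            "r_s": rs[:, k].tolist(),
            "median_r_s": float(np.median(rs[:, k])),
            "W": w,
            "p_one_tailed_greater": p,
            "p_one_tailed_less": wilcoxon_signed_rank(rs[:, k], alternative="less")[1],
            "median_r_s_residualized": float(np.median(rs_res[:, k])),
            "W_residualized": w_res,
            "p_residualized": p_res,
            "median_slope": float(np.median(slopes[:, k])),
            "median_intercept": float(np.median(intercepts[:, k])),
            "lesion_size_r": size_r,
            "lesion_size_p": size_p,
        }

    w_a, p_a = wilcoxon_signed_rank(anat_r, alternative="greater")
    report["anatomical_control"] = {
        "anat_r": anat_r.tolist(),
        "median_anat_r": float(np.median(anat_r)),
        "W": w_a,
        "p_one_tailed": p_a,
    }

    change_labels = None
    if clinical is not None:
        cl = clinical
        missing = cl[["nihss_day0", "nihss_day5"]].isna().any(axis=1)
        if missing.any():
            report["warnings"].append(f"{int(missing.sum())} patient(s) missing NIHSS; excluded from clinical blocks")
        cl = cl[~missing]
        changed = (cl["nihss_day0"] != cl["nihss_day5"]).to_numpy()
        if changed.any() and (~changed).any():
            change_labels = {"ids": list(cl.index), "changed": changed}
        else:
            report["warnings"].append("clinical-change grouping degenerate; bin analysis skipped")
    else:
        report["warnings"].append("no clinical table; clinical blocks skipped")

    has_bins = all("delta_concordance" in p for p in patient_results)
    if change_labels is not None and has_bins:
        id_to_res = {p["patient_id"]: p for p in patient_results}
        usable = [pid for pid in change_labels["ids"] if pid in id_to_res]
        changed = np.array(
            [change_labels["changed"][change_labels["ids"].index(pid)] for pid in usable]
        )
        labels = np.where(changed, "change", "no_change")
        bin_keys = sorted(patient_results[0]["delta_concordance"], key=int)
        child_seeds = np.random.SeedSequence(seed).spawn(K * len(bin_keys))
        si = 0
        for k in range(K):
            grad_block = {}
            for nb in bin_keys:
                deltas = np.array([id_to_res[pid]["delta_concordance"][nb][k] for pid in usable])
                ok = ~np.isnan(deltas)
                d, l = deltas[ok], labels[ok]
                sub_seed = int(child_seeds[si].generate_state(1)[0] % (2**31))
                si += 1
                if (l == "change").sum() == 0 or (l == "no_change").sum() == 0:
                    report["warnings"].append(f"gradient {k + 1}, {nb} bins: one group empty after NaN removal")
                    continue
                diff = float(d[l == "change"].mean() - d[l == "no_change"].mean())
                perm_p = permutation_group_diff(d, l, n_perm=n_perm, seed=sub_seed, alternative="greater")
                grad_block[nb] = {
                    "group_diff": diff,
                    "perm_p": perm_p,
                    "mean_change": float(d[l == "change"].mean()),
                    "mean_no_change": float(d[l == "no_change"].mean()),
                    "n_change": int((l == "change").sum()),
                    "n_no_change": int((l == "no_change").sum()),
                }
            report["bin_analysis"][str(k + 1)] = grad_block

    if clinical is not None:
        cl = clinical.dropna()
        id_to_row = {p["patient_id"]: i for i, p in enumerate(patient_results)}
        usable = [pid for pid in cl.index if pid in id_to_row]
        if len(usable) >= 5:
            rows = [id_to_row[pid] for pid in usable]
            score_cols = {
                ("mrs", "admission"): "mrs_day0",
                ("nihss", "admission"): "nihss_day0",
                ("mrs", "discharge"): "mrs_day5",
                ("nihss", "discharge"): "nihss_day5",
            }
            for k in range(K):
                block = {}
                for meas_name, meas in (("slope", slopes), ("intercept", intercepts)):
                    for (score, tp), col in score_cols.items():
                        try:
                            tau, p = kendall_clinical(meas[rows, k], cl.loc[usable, col].to_numpy())
                        except ValueError as e:
                            tau, p = None, None
                            report["warnings"].append(
                                f"gradient {k + 1} {meas_name} vs {col}: {e}"
                            )
                        block[f"{meas_name}_{score}_{tp}"] = {"tau": tau, "p": p}
                report["clinical_association"][str(k + 1)] = block
        else:
            report["warnings"].append("fewer than 5 patients with complete clinical scores")

    for w in report["warnings"]:
        logger.warning(w)
    return report
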