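"""Calibration and recovery experiments on the synthetic study generator.

Each function runs one self-contained validation of the analysis chain —
parameter recovery of the logistic fit, null calibration of the outcome
classifier, planted-effect detection, cluster recovery and stability,
fold-change recovery, ANOVA calibration, and the end-to-end determinism of
the full pipeline — and returns the measured quantities.  All randomness
derives from the single ``seed`` argument through ``SeedSequence`` spawn
keys, so every experiment is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.integrate import quad

from . import interactions
from .clustering import bootstrap_stability, cluster_matrix
from .config import PipelineConfig
from .foldchange import test_fold_changes
from .growth import LogisticGrowthModel, logistic_od
from .io_plate import GrowthCurve
from .monoculture import nested_anova
from .pipeline import fit_dataset, run_all
from .simulate import emit_dataset, neutral_scenario, planted_block_matrix

TIMES = np.arange(0.0, 24.01, 0.5)


def _seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0] % (2**31))


def fit_recovery(seed: int, n_noiseless: int = 200, n_noisy: int = 100,
                 sigma: float = 0.02) -> dict:
    """Logistic parameter recovery, noiseless and at plate-reader noise.

    Noiseless curves span K in [1, 2.5], r in [0.15, 0.5] h^-1 and N0 in
    [0.005, 0.02]; noisy curves use the canonical (K=2, r=0.4, N0=0.01)
    phenotype with additive Gaussian OD noise.  Also audits the closed-form
    AUC of every converged fit against adaptive quadrature.
    """
    rng = np.random.default_rng(_seed(seed, 1))
    max_rel_err = 0.0
    auc_max_rel_dev = 0.0

    def audit_auc(res):
        nonlocal auc_max_rel_dev
        oracle, _ = quad(lambda t: logistic_od(t, res.K, res.r, res.N0), 0.0, 24.0,
                         epsrel=1e-12, limit=200)
        auc_max_rel_dev = max(auc_max_rel_dev, abs(res.auc(24.0) - oracle) / oracle)

    for _ in range(n_noiseless):
        K = rng.uniform(1.0, 2.5)
        r = rng.uniform(0.15, 0.5)
        N0 = rng.uniform(0.005, 0.02)
        res = LogisticGrowthModel(TIMES, logistic_od(TIMES, K, r, N0)).fit()
        assert res.converged
        max_rel_err = max(max_rel_err,
                          abs(res.K - K) / K, abs(res.r - r) / r, abs(res.N0 - N0) / N0)
        audit_auc(res)

    r_errs = []
    for _ in range(n_noisy):
        od = np.clip(logistic_od(TIMES, 2.0, 0.4, 0.01) + rng.normal(0, sigma, TIMES.shape),
                     0.0, None)
        res = LogisticGrowthModel(TIMES, od).fit()
        if res.converged:
            r_errs.append(abs(res.r - 0.4) / 0.4)
            audit_auc(res)
    return {
        "noiseless_max_rel_err": float(max_rel_err),
        "noisy_r_median_rel_err": float(np.median(r_errs)),
        "auc_max_rel_dev": float(auc_max_rel_dev),
        "n_noiseless": n_noiseless,
        "n_noisy": len(r_errs),
    }


def classifier_null_calibration(seed: int, n_datasets: int = 5) -> dict:
    """Outcome-class rates for AUC under the shared-niche neutral null.

    Runs ``n_datasets`` independent full designs end to end (simulate ->
    fit -> classify), pooling 105 cocultures each.
    """
    counts = {"A": 0, "B": 0, "C": 0, "D": 0}
    for d in range(n_datasets):
        ds = emit_dataset(neutral_scenario(seed=_seed(seed, 2, d)))
        joined = [(ds.layout[c.culture_id], c) for c in ds.curves]
        params = fit_dataset(joined, PipelineConfig(seed=_seed(seed, 2, d)))
        recs = interactions.analyze_all(params, parameters=("auc",))
        for rec in recs:
            counts[rec.outcome] += 1
    n = sum(counts.values())
    return {
        "a_rate": counts["A"] / n,
        "b_rate": counts["B"] / n,
        "c_rate": counts["C"] / n,
        "n": n,
    }


def planted_effect_detection(seed: int, effect: float = 0.30) -> dict:
    """Sign recovery for cocultures whose AUC is shifted by ``effect``.

    Coculture OD curves of a neutral design are scaled by (1 +/- effect)
    — which scales the logistic AUC exactly — then refitted and indexed
    against the unscaled monocultures.  Extreme cases (x1.5 / x0.5, low
    noise) must reach the over-/underyielding classes.
    """
    ds = emit_dataset(neutral_scenario(seed=_seed(seed, 3)))
    joined = [(ds.layout[c.culture_id], c) for c in ds.curves]
    cfg = PipelineConfig(seed=_seed(seed, 3))
    base = fit_dataset(joined, cfg)
    correct = 0
    total = 0
    for factor, want in ((1.0 + effect, 1), (1.0 - effect, -1)):
        scaled_curves = [
            GrowthCurve(c.culture_id, c.times, c.od * factor) if
            ds.layout[c.culture_id].kind == "coculture" else c
            for c in ds.curves
        ]
        params = fit_dataset([(ds.layout[c.culture_id], c) for c in scaled_curves], cfg)
        params.loc[params["kind"] == "monoculture", ["auc"]] = \
            base.loc[base["kind"] == "monoculture", ["auc"]]
        for rec in interactions.analyze_all(params, parameters=("auc",)):
            total += 1
            correct += int(np.sign(rec.index) == want)

    # extreme planted cases at low noise must reach classes B and C
    ds_lo = emit_dataset(neutral_scenario(seed=_seed(seed, 3, 1), sigma_od=0.005))
    joined_lo = [(ds_lo.layout[c.culture_id], c) for c in ds_lo.curves]
    base_lo = fit_dataset(joined_lo, cfg)
    extreme = {"B": 0, "C": 0, "n": 10}
    pair_keys = sorted({(r.strain_1, r.strain_2)
                        for r in interactions.analyze_all(base_lo, parameters=("auc",))})[:extreme["n"]]
    for factor, cls in ((1.5, "B"), (0.5, "C")):
        curves = [GrowthCurve(c.culture_id, c.times, c.od * factor)
                  if ds_lo.layout[c.culture_id].kind == "coculture" else c
                  for c in ds_lo.curves]
        params = fit_dataset([(ds_lo.layout[c.culture_id], c) for c in curves], cfg)
        recs = {(r.strain_1, r.strain_2): r
                for r in interactions.analyze_all(params, parameters=("auc",))}
        for key in pair_keys:
            extreme[cls] += int(recs[key].outcome == cls)
    return {
        "sign_recovery_rate": correct / total,
        "n": total,
        "extreme_overyield_rate": extreme["B"] / extreme["n"],
        "extreme_underyield_rate": extreme["C"] / extreme["n"],
    }


def cluster_recovery(seed: int, B: int = 100) -> dict:
    """Planted 5-species-block matrix: exact recovery plus stability."""
    from sklearn.metrics import adjusted_rand_score

    mat, labels = planted_block_matrix(seed=_seed(seed, 4), separation=5.0, within_sd=1.0)
    assignments, _ = cluster_matrix(mat, 5)
    ari = adjusted_rand_score(labels, [assignments[s] for s in mat.strains])
    stab = bootstrap_stability(mat, 5, B=B, method="bootstrap", seed=_seed(seed, 4, 1))

    mat_hi, _ = planted_block_matrix(seed=_seed(seed, 4), separation=50.0, within_sd=1.0)
    stab_hi = bootstrap_stability(mat_hi, 5, B=B, method="bootstrap", seed=_seed(seed, 4, 1))
    monotone = all(stab_hi.jaccard[c] >= stab.jaccard[c] - 1e-12 for c in stab.jaccard)
    return {
        "ari": float(ari),
        "min_mean_jaccard": float(min(stab.jaccard.values())),
        "stability_monotone": bool(monotone),
        "B": B,
    }


def foldchange_recovery(seed: int, n_events: int = 10_000, n_reps: int = 4,
                        n_null: int = 1000, alpha: float = 0.05) -> dict:
    """Fold-change estimation against planted share shifts.

    Plants T24 shares of 1/3 (focal declining) and 2/3 (focal rising) from
    a 50:50 inoculum, draws multinomial counts, and checks the estimated
    mean fold change against the planted value within 3 SEs; verifies the
    two-gate reciprocity identity exactly; and measures the rejection rate
    of the no-change test under a unit-mean null.
    """
    rng = np.random.default_rng(_seed(seed, 5))
    out = {}
    for label, p24 in (("down", 1.0 / 3.0), ("up", 2.0 / 3.0)):
        fcs = []
        recip_dev = 0.0
        for _ in range(n_reps):
            a0 = rng.multinomial(n_events, [0.5, 0.5])[0] / n_events
            a24 = rng.multinomial(n_events, [p24, 1 - p24])[0] / n_events
            fcs.append(a24 / a0)
            f_other = (1 - a24) / (1 - a0)
            recip_dev = max(recip_dev, abs(fcs[-1] * a0 + f_other * (1 - a0) - 1.0))
        truth = p24 / 0.5
        # delta-method SE of one replicate fold change
        se_rep = truth * np.sqrt(p24 * (1 - p24) / n_events / p24**2
                                 + 0.25 / n_events / 0.25)
        out[f"mean_fc_{label}"] = float(np.mean(fcs))
        out[f"planted_fc_{label}"] = truth
        out[f"se3_{label}"] = float(3 * se_rep / np.sqrt(n_reps))
        out[f"reciprocity_max_dev_{label}"] = float(recip_dev)

    rejections = 0
    for _ in range(n_null):
        fcs = rng.normal(1.0, 0.1, size=n_reps)
        _, _, p = test_fold_changes(np.abs(fcs), alpha=alpha)
        rejections += p < alpha
    out["null_rejection_rate"] = rejections / n_null
    out["n_null"] = n_null
    return out


def anova_calibration(seed: int, n_power: int = 200, n_null: int = 500) -> dict:
    """Power, type-I rate and one-way equivalence of the nested ANOVA."""
    rng = np.random.default_rng(_seed(seed, 6))

    def design(species_means, strain_sd, resid_sd, n_strains=3, n_reps=3):
        vals, sp, st_ = [], [], []
        for s, mu in species_means.items():
            for k in range(n_strains):
                m = mu + rng.normal(0, strain_sd)
                for _ in range(n_reps):
                    vals.append(m + rng.normal(0, resid_sd))
                    sp.append(s)
                    st_.append(f"{s}{k}")
        return np.array(vals), np.array(sp), np.array(st_)

    power_hits = 0
    for _ in range(n_power):
        v, sp, st_ = design({"A": 0.0, "B": 10.0}, strain_sd=0.0, resid_sd=1.0)
        power_hits += nested_anova(v, sp, st_).species_p < 0.01

    type1_hits = 0
    for _ in range(n_null):
        v, sp, st_ = design({s: 0.0 for s in "ABCDE"}, strain_sd=0.5, resid_sd=1.0)
        type1_hits += nested_anova(v, sp, st_).species_p < 0.05

    # single-strain-per-species design must reproduce one-way ANOVA
    groups = [rng.normal(m, 1.0, size=4) for m in (0.0, 0.4, 1.1, 2.0, 0.3)]
    v = np.concatenate(groups)
    sp = np.repeat(list("ABCDE"), 4)
    res = nested_anova(v, sp, sp)
    F, _ = stats.f_oneway(*groups)
    return {
        "power": power_hits / n_power,
        "type1_rate": type1_hits / n_null,
        "oneway_F_abs_diff": float(abs(res.species_F - F)),
        "n_power": n_power,
        "n_null": n_null,
    }


def end_to_end(seed: int, workdir) -> dict:
    """Full design through ``run_all`` twice: conservation and determinism."""
    workdir = Path(workdir)
    data_dir = workdir / "data"
    out_dir = workdir / "out"
    emit_dataset(neutral_scenario(seed=_seed(seed, 7)), data_dir)
    cfg = PipelineConfig(input_dir=str(data_dir), output_dir=str(out_dir),
                         seed=_seed(seed, 7))
    t0 = time.time()
    result = run_all(cfg)
    elapsed = time.time() - t0

    def hashes():
        return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(out_dir.iterdir()) if p.is_file()}

    first = hashes()
    run_all(cfg)
    identical = hashes() == first
    sums = {p: int(g["count"].sum()) for p, g in result.summary.groupby("parameter")}
    return {
        "runtime_s": float(elapsed),
        "outcome_sums": sums,
        "all_sums_105": all(v == 105 for v in sums.values()),
        "rerun_hash_identical": bool(identical),
    }
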