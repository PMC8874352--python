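"""Two-cohort pipeline orchestration and cohort-level comparisons.

Runs protocol generation, synthetic cohort generation, blink detection,
entrainment spectra, histogram fitting and distance testing, hazard-rate
slope clusters, and saccade scoring end-to-end from a single seeded
configuration, and produces the cohort-level statistics: one-sided
rank-sum tests on blink counts and median inter-blink intervals, a
bisquare robust regression relating paired counts between groups, Spearman
correlation of counts with age, and a Kolmogorov-Smirnov normality screen.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import blink_detect, distfit, hazard_slopes, protocol as proto, \
    saccade_em, spectral, synth_eog

log = logging.getLogger("blinkhazard")

IQR_FACTOR = 3.0


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str
    age: float
    blink_count: int = 0
    median_ibi_ms: float = np.nan
    pair_id: Optional[str] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    catalog: Optional[blink_detect.BlinkCatalog] = None
    spectrum: Optional[spectral.SpectrumResult] = None
    distribution: Optional[distfit.BinnedDistribution] = None
    peristim: Optional[hazard_slopes.PeristimMatrix] = None
    saccades: list = field(default_factory=list)


def outlier_exclusion(records: list[ParticipantRecord],
                      factor: float = IQR_FACTOR,
                      paired: bool = True) -> list[ParticipantRecord]:
    """Exclude participants whose blink count exceeds their group's upper
    quartile by more than ``factor`` x IQR, together with their matched
    partner when pairing is requested."""
    by_group: dict[str, list[ParticipantRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    flagged: list[ParticipantRecord] = []
    for grp in by_group.values():
        counts = np.array([r.blink_count for r in grp], dtype=float)
        q1, q3 = np.percentile(counts, [25, 75])
        upper = q3 + factor * (q3 - q1)
        for r in grp:
            if r.blink_count > upper:
                r.excluded = True
                r.exclusion_reason = (
                    f"blink count {r.blink_count} > Q3 + {factor}xIQR "
                    f"({upper:.1f})")
                flagged.append(r)
    if paired:
        by_id = {r.participant_id: r for r in records}
        for r in flagged:
            if r.pair_id is None:
                raise ValueError(
                    f"paired removal requested but {r.participant_id} "
                    "has no matched partner")
            partner = by_id.get(r.pair_id)
            if partner is None:
                raise ValueError(f"partner {r.pair_id} not found")
            if not partner.excluded:
                partner.excluded = True
                partner.exclusion_reason = (
                    f"matched partner of excluded {r.participant_id}")
    return [r for r in records if not r.excluded]


def _robust_regression(x: np.ndarray, y: np.ndarray) -> dict:
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "t": float(fit.tvalues[1]),
        "p": float(fit.pvalues[1]),
    }


def cohort_tests(records: list[ParticipantRecord],
                 group_a: str, group_b: str,
                 conventional_r: bool = False) -> dict:
    """Cohort-level comparisons between two groups (A assumed to outperform
    B under the one-sided alternatives)."""
    a = [r for r in records if r.group == group_a and not r.excluded]
    b = [r for r in records if r.group == group_b and not r.excluded]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 participants per group")
    ca = np.array([r.blink_count for r in a], dtype=float)
    cb = np.array([r.blink_count for r in b], dtype=float)
    ia = np.array([r.median_ibi_ms for r in a], dtype=float)
    ib = np.array([r.median_ibi_ms for r in b], dtype=float)
    n_tot = len(a) + len(b)

    def one_sided(x, y, alternative="greater"):
        res = stats.ranksums(x, y, alternative=alternative)
        z = float(res.statistic)
        r = z / np.sqrt(n_tot) if conventional_r else z / n_tot
        return {"z": z, "p": float(res.pvalue), "r": r}

    report: dict = {
        "n": {"group_a": len(a), "group_b": len(b)},
        "counts": {
            "group_a_median": float(np.median(ca)),
            "group_b_median": float(np.median(cb)),
            "rank_sum": one_sided(ca, cb),
        },
        "ibi_ms": {
            "group_a_median": float(np.nanmedian(ia)),
            "group_b_median": float(np.nanmedian(ib)),
            # shorter intervals = more blinking: test A < B
            "rank_sum": one_sided(ia, ib, alternative="less"),
        },
    }

    # normality screen motivating the non-parametric tests
    pooled = np.concatenate([ca, cb])
    if pooled.std() > 0:
        ks = stats.kstest((pooled - pooled.mean()) / pooled.std(), "norm")
        report["ks_normality"] = {"stat": float(ks.statistic),
                                  "p": float(ks.pvalue)}

    # paired robust regression of group-B counts on group-A counts
    a_by_id = {r.participant_id: r for r in a}
    matched = [(a_by_id[r.pair_id], r) for r in b
               if r.pair_id in a_by_id]
    if len(matched) >= 3:
        xa = np.array([m[0].blink_count for m in matched], dtype=float)
        xb = np.array([m[1].blink_count for m in matched], dtype=float)
        report["paired_count_regression"] = _robust_regression(xa, xb)
    else:
        log.warning("pairing absent or too sparse; paired regression skipped")
        report["paired_count_regression"] = None

    # age effect on the across-group mean counts
    ages = np.array([r.age for r in a + b], dtype=float)
    counts = np.concatenate([ca, cb])
    if np.isfinite(ages).all() and len(set(ages)) > 1:
        rho, p = stats.spearmanr(ages, counts)
        report["age_spearman"] = {"rho": float(rho), "p": float(p)}
        report["age_robust_regression"] = _robust_regression(ages, counts)
    return report


# ---------------------------------------------------------------------------
# end-to-end pipeline

DEFAULT_CONFIG = {
    "seed": 0,
    "protocol": {"n_sequences": 240, "n_target_sequences": 60,
                 "soa_ms": 750.0},
    "groups": {
        "HC-like": {},
        "PD-like": dict(synth_eog.PD_LIKE_OVERRIDES),
    },
    "n_per_group": 15,
    "noise_sd": 5.0,
    "render": False,        # True: full waveform synthesis + detection
    "n_boot": 1000,
    "n_perm": 2000,
    "saccade_rate_hz": 0.15,
    "saccade_rate_sd": {"HC-like": 0.0, "PD-like": 0.05},
}


def _manifest_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: Optional[dict] = None,
                 out_dir: Optional[Path] = None) -> dict:
    """Run the full two-cohort analysis from a seeded configuration.

    With ``render=False`` blink catalogs are built directly from the
    sampled ground-truth blink times (fast path used for statistical
    studies); with ``render=True`` continuous recordings are synthesized
    and passed through the waveform detector.

    Returns the result tree; when ``out_dir`` is given, TSV/JSON artifacts
    and a manifest are written there.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        for k, v in config.items():
            cfg[k] = v
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    group_seeds = {g: int(s.generate_state(1)[0] % (2 ** 31))
                   for g, s in zip(sorted(cfg["groups"]), ss.spawn(
                       len(cfg["groups"])))}

    prot = proto.generate_protocol(seed=seed, **cfg["protocol"])
    records: list[ParticipantRecord] = []
    per_group: dict[str, dict] = {}

    for group in sorted(cfg["groups"]):
        overrides = cfg["groups"][group]
        cohort = synth_eog.generate_cohort(
            n_participants=int(cfg["n_per_group"]), protocol=prot,
            seed=group_seeds[group], group=group,
            model_overrides=overrides, render=bool(cfg["render"]),
            noise_sd=float(cfg["noise_sd"]),
            saccade_rate_hz=float(cfg["saccade_rate_hz"]),
            saccade_rate_sd=float(
                cfg["saccade_rate_sd"].get(group, 0.0)
                if isinstance(cfg["saccade_rate_sd"], dict)
                else cfg["saccade_rate_sd"]))
        g_records = []
        for i, p in enumerate(cohort):
            if cfg["render"]:
                catalog = blink_detect.select_best_signal(
                    p.recording, participant_id=p.participant_id)
            else:
                catalog = blink_detect.catalog_from_peak_times(
                    p.blink_times_ms, participant_id=p.participant_id)
            epochs = spectral.extract_epochs(catalog, prot)
            vec = spectral.timeline_vector(epochs,
                                           duration_ms=prot.duration_ms)
            spec = spectral.fft_power(vec)
            dist = distfit.bin_and_smooth(epochs)
            peri = hazard_slopes.build_peristim(epochs)
            ibis = catalog.inter_blink_intervals_ms()
            sacc_events: list = []
            if cfg["render"]:
                h = saccade_em.horizontal_trace(p.recording.channels)
                try:
                    model = saccade_em.train_feature_model(
                        h, p.recording.fs, seed=seed)
                    sacc_events = saccade_em.score_events(
                        h, model, p.recording.fs, blink_catalog=catalog)
                except ValueError as e:
                    log.warning("saccade model skipped for %s: %s",
                                p.participant_id, e)
            rec = ParticipantRecord(
                participant_id=p.participant_id, group=group, age=p.age,
                blink_count=catalog.n_used,
                median_ibi_ms=float(np.median(ibis)) if len(ibis) else np.nan,
                pair_id=None, catalog=catalog, spectrum=spec,
                distribution=dist, peristim=peri, saccades=sacc_events)
            g_records.append(rec)
        per_group[group] = {"records": g_records}
        records.extend(g_records)

    # age/gender-matched pairing by within-group order
    groups = sorted(cfg["groups"])
    if len(groups) == 2:
        ra = per_group[groups[0]]["records"]
        rb = per_group[groups[1]]["records"]
        for x, y in zip(ra, rb):
            x.pair_id = y.participant_id
            y.pair_id = x.participant_id

    kept = outlier_exclusion(records, paired=len(groups) == 2)

    results: dict = {"config": cfg, "protocol_validation":
                     proto.validate_protocol(prot).__dict__}
    ga, gb = groups[0], groups[1]
    kept_a = [r for r in kept if r.group == ga]
    kept_b = [r for r in kept if r.group == gb]
    results["cohort"] = cohort_tests(kept, ga, gb)
    results["entrainment"] = spectral.entrainment_stats(
        [r.spectrum for r in kept_a], [r.spectrum for r in kept_b])

    mat_a = np.array([r.distribution.smoothed for r in kept_a])
    mat_b = np.array([r.distribution.smoothed for r in kept_b])
    med_a = distfit.group_median_distribution(mat_a)
    med_b = distfit.group_median_distribution(mat_b)
    fit_a = distfit.fit_five_gaussians(med_a)
    fit_b = distfit.fit_five_gaussians(med_b)
    dtest = distfit.bootstrap_distance_test(
        mat_a, mat_b, n=int(cfg["n_boot"]), seed=seed)
    pa = np.array([r.distribution.pristine for r in kept_a])
    pb = np.array([r.distribution.pristine for r in kept_b])
    interval_tests = distfit.per_interval_peak_tests(pa, pb, fit_a)
    results["distributions"] = {
        "fit_a": {"means_ms": fit_a.means_ms.tolist(),
                  "sigmas_ms": fit_a.sigmas_ms.tolist(),
                  "amplitudes": fit_a.amplitudes.tolist(),
                  "iterations": fit_a.iterations,
                  "mean_residual": fit_a.mean_residual},
        "fit_b": {"means_ms": fit_b.means_ms.tolist(),
                  "sigmas_ms": fit_b.sigmas_ms.tolist(),
                  "amplitudes": fit_b.amplitudes.tolist(),
                  "iterations": fit_b.iterations,
                  "mean_residual": fit_b.mean_residual},
        "chi2_distance": dtest.distance,
        "distance_p": dtest.p_value,
        "per_interval": interval_tests,
    }

    results["clusters"] = {}
    for gname, grp in (("group_a", kept_a), ("group_b", kept_b)):
        slopes = hazard_slopes.slope_map([r.peristim for r in grp])
        cres = hazard_slopes.cluster_permutation_test(
            slopes, n_perm=int(cfg["n_perm"]), seed=seed)
        results["clusters"][gname] = {
            "threshold_t": cres.threshold,
            "clusters": [{"start_ms": c.start_ms, "stop_ms": c.stop_ms,
                          "mass": c.mass, "p": c.p_value}
                         for c in cres.clusters],
        }

    if cfg["render"]:
        results["saccades"] = saccade_em.variance_compare(
            [r.saccades for r in kept_a], [r.saccades for r in kept_b])

    results["exclusions"] = [
        {"participant": r.participant_id, "reason": r.exclusion_reason}
        for r in records if r.excluded]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prot.to_tsv(out_dir / "events.tsv")
        counts = pd.DataFrame(
            [{"participant": r.participant_id, "group": r.group,
              "age": round(r.age, 3), "blink_count": r.blink_count,
              "median_ibi_ms": round(r.median_ibi_ms, 3)
              if np.isfinite(r.median_ibi_ms) else np.nan,
              "excluded": r.excluded}
             for r in records])
        counts.to_csv(out_dir / "participants.tsv", sep="\t", index=False)
        np.savetxt(out_dir / "median_curve_a.tsv",
                   np.column_stack([distfit.BIN_CENTERS, med_a]),
                   delimiter="\t", header="bin_center_ms\tfrequency",
                   comments="", fmt="%.6g")
        np.savetxt(out_dir / "median_curve_b.tsv",
                   np.column_stack([distfit.BIN_CENTERS, med_b]),
                   delimiter="\t", header="bin_center_ms\tfrequency",
                   comments="", fmt="%.6g")
        serializable = json.loads(json.dumps(results, default=_jsonify,
                                             sort_keys=True))
        with open(out_dir / "report.json", "w") as fh:
            json.dump(serializable, fh, indent=2, sort_keys=True)
        manifest = {
            "seed": seed,
            "config_hash": _manifest_hash(cfg),
            "report_hash": _manifest_hash(serializable),
            "exclusions": results["exclusions"],
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
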