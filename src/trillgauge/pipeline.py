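"""End-to-end study orchestration: simulate -> measure -> paternity ->
phenotype -> statistics, emitting table-shaped CSV outputs and a report.

The full battery mirrors the study design:

* locus summaries (descriptive genetics table),
* repeatability of vocal deviation and trill consistency, and the
  within/between-male association between them,
* male quality vs. trill quality (one mixed model per quality measure and
  trait, acoustic covariates controlled),
* trill and male quality vs. mating success (polygyny, within-pair
  paternity, extra-pair success),
* paired comparisons of extra-pair sires and the males they cuckolded,
* annual reproductive success vs. trill quality, male quality and mating
  success,

with Benjamini-Hochberg FDR applied table-wise and standardized effect
sizes (partial r / Cohen's d with noncentral CIs) on every row.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trillgauge import audio_features as af
from trillgauge import paternity as pat
from trillgauge import performance as perf
from trillgauge import phenotype as phen
from trillgauge import stats as tgstats
from trillgauge import synthetic_data as synth
from trillgauge.stats import ModelSpec

log = logging.getLogger("trillgauge")

__all__ = ["RunConfig", "ResultBundle", "measure_bundle", "run_study", "make_report"]

QUALITY_MEASURES = [
    "tarsus",
    "wing",
    "tail",
    "condition",
    "age_asy",
    "hl_ratio",
    "bactericidal",
    "song_rate",
    "flights",
    "time_close",
]
CATEGORICAL_QUALITY = {"age_asy"}
TRAIT_RESPONSES = {"deviation": None, "consistency": "neg_log_1m"}
SUCCESS_MEASURES = {
    "polygyny": ("polygynous", "categorical"),
    "wp": ("wp_proportion", "continuous"),
    "ep": ("ep_success", "categorical"),
}


@dataclass
class RunConfig:
    """One reproducible run: simulation settings, measurement presets,
    statistical knobs, seed, output directory."""

    population: synth.PopulationConfig = field(default_factory=synth.PopulationConfig)
    audio: bool = False  # True: render audio and measure it; False: tabular measures
    bin_width: float = 2.0
    fdr_q: float = 0.05
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        self.population.seed = self.seed


@dataclass
class ResultBundle:
    config: RunConfig
    bundle: synth.StudyBundle
    measures: pd.DataFrame
    limit: perf.PerformanceLimit
    calls: pd.DataFrame
    success: pd.DataFrame
    covariates: pd.DataFrame
    locus_summary: pd.DataFrame
    repeatability: pd.DataFrame
    decomposition: pd.DataFrame
    battery: pd.DataFrame
    paired: pd.DataFrame
    recovery: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "locus_summary": self.locus_summary,
            "repeatability": self.repeatability,
            "trait_association": self.decomposition,
            "quality_vs_trills": self.battery[self.battery.table == "quality_vs_trills"],
            "polygyny": self.battery[self.battery.table == "polygyny"],
            "wp_success": self.battery[self.battery.table == "wp_success"],
            "ep_success": self.battery[self.battery.table == "ep_success"],
            "paired_epwp": self.paired,
            "reproductive_success": self.battery[
                self.battery.table == "reproductive_success"
            ],
        }

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
        self.measures.to_csv(out / "measures.csv", index=False, float_format="%.6g")
        self.calls.to_csv(out / "paternity_calls.csv", index=False)
        self.success.to_csv(out / "male_year_success.csv", index=False, float_format="%.6g")
        with open(out / "recovery.json", "w") as fh:
            json.dump(self.recovery, fh, indent=1, sort_keys=True, default=float)
        (out / "report.txt").write_text(make_report(self))
        return out


# ---------------------------------------------------------------------------
# measurement stage
# ---------------------------------------------------------------------------


def measure_waveform(
    waveform: np.ndarray, sample_rate: float, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Measure every annotated trill in one recording: acoustic measures on
    the fine-grid preset plus consistency from the correlation preset."""
    meas = af.measure_annotation_table(waveform, sample_rate, annotations)
    cons = []
    for (_, trill_id), syl in annotations.groupby(["song_id", "trill_id"], sort=True):
        specs = []
        freqs = None
        for _, row in syl.sort_values("begin_s").iterrows():
            seg = af._segment(waveform, sample_rate, row.begin_s, row.end_s)
            f, _, mag = af.spectrogram(seg, sample_rate, af.CORRELATION_PRESET)
            freqs = f
            specs.append(mag)
        row0 = meas[meas.trill_id == trill_id].iloc[0]
        c = perf.trill_consistency(
            specs, freqs, freq_bounds=(row0.low_hz, row0.high_hz)
        )
        cons.append({"trill_id": trill_id, "consistency": c})
    return meas.merge(pd.DataFrame(cons), on="trill_id")


def measure_bundle(bundle: synth.StudyBundle, audio: bool) -> pd.DataFrame:
    """Per-trill measures table for a whole bundle.

    Audio mode renders each male-year recording, measures it, and discards
    the waveform; tabular mode uses the generator's measurement-noise-added
    measures directly.  Output columns are identical either way.
    """
    if not audio:
        m = bundle.measures.copy()
        m = m.rename(columns={"rate": "rate", "bandwidth": "bandwidth"})
        return m
    frames = []
    sr = bundle.config.sample_rate
    for _, my in bundle.male_years.iterrows():
        wave, ann = bundle.render_male_year(my.male_id, int(my.year))
        m = measure_waveform(wave, sr, ann)
        m.insert(0, "male_id", my.male_id)
        m.insert(1, "year", int(my.year))
        frames.append(m)
    log.info("measured %d male-year recordings", len(frames))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# statistics battery
# ---------------------------------------------------------------------------


def _acoustic_terms(data: pd.DataFrame) -> list[str]:
    terms = []
    if data["year"].nunique() > 1:
        terms.append("C(year)")
    if data["trill_type"].nunique() > 1:
        terms.append("C(trill_type)")
    terms += ["pitch", "duration", "time_in_song"]
    return terms


def _effect_size_row(est_row, kind: str, n1: int | None = None, n2: int | None = None):
    t, df = est_row.stat, est_row.df
    if not np.isfinite(t):
        return np.nan, np.nan, np.nan, "partial_r"
    if not np.isfinite(df):
        df = max((n1 or 2) + (n2 or 2) - 2, 2)
    if kind == "cohens_d" and n1 and n2:
        es = tgstats.cohens_d(t=float(t), n1=int(n1), n2=int(n2))
    else:
        es = tgstats.effect_partial_r(float(t), float(df))
    return es.value, es.ci_low, es.ci_high, es.kind


def _battery_row(table, response, predictor, res, est_row, kind, n1=None, n2=None):
    val, lo, hi, es_kind = _effect_size_row(est_row, kind, n1, n2)
    return {
        "table": table,
        "response": response,
        "predictor": predictor,
        "estimate": est_row.estimate,
        "se": est_row.se,
        "stat": est_row.stat,
        "df": est_row.df,
        "p": est_row.p,
        "effect_size": val,
        "effect_ci_low": lo,
        "effect_ci_high": hi,
        "effect_kind": es_kind,
        "n_obs": res.n_obs,
        "n_groups": res.n_groups,
        "family": res.family,
    }


def _trill_model(table, trait, transform_name, predictor, trill_df, battery, kind,
                 n1=None, n2=None, pred_term=None):
    data = trill_df.dropna(subset=[predictor, trait]).copy()
    if data.empty or data[predictor].nunique() < 2:
        return
    fixed = [pred_term or predictor] + _acoustic_terms(data)
    spec = ModelSpec(response=trait, fixed=fixed, group="male_id", transform=transform_name)
    try:
        res = tgstats.fit_mixed(spec, data)
        est = res.term(predictor)
    except (ValueError, KeyError, np.linalg.LinAlgError) as err:
        log.warning("model %s ~ %s failed: %s", trait, predictor, err)
        return
    battery.append(_battery_row(table, trait, predictor, res, est, kind, n1, n2))


def run_battery(
    trills: pd.DataFrame,
    covariates: pd.DataFrame,
    success: pd.DataFrame,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """The model roster: quality vs trills, mating success, reproductive
    success; returns one tidy row per test with FDR flags."""
    battery: list[dict] = []
    mj = trills.merge(covariates, on=["male_id", "year"], how="left").merge(
        success, on=["male_id", "year"], how="left"
    )
    my = covariates.merge(success, on=["male_id", "year"], how="left")
    my["rs_t"] = tgstats.transform("sqrt_plus1", my["annual_rs"].fillna(np.nan))

    # ---- quality vs trill measures -----------------------------------
    for quality in QUALITY_MEASURES:
        if quality not in mj or mj[quality].dropna().nunique() < 2:
            continue
        for trait, tr in TRAIT_RESPONSES.items():
            kind = "cohens_d" if quality in CATEGORICAL_QUALITY else "partial_r"
            sub = mj.dropna(subset=[quality, trait])
            n1 = n2 = None
            if kind == "cohens_d":
                lv = sub.groupby(quality)["male_id"].nunique()
                if len(lv) == 2:
                    n1, n2 = int(lv.iloc[0]), int(lv.iloc[1])
            _trill_model("quality_vs_trills", trait, tr, quality, mj, battery, kind, n1, n2)

    # ---- mating success ----------------------------------------------
    for table, (col, flavor) in SUCCESS_MEASURES.items():
        tname = {"polygyny": "polygyny", "wp": "wp_success", "ep": "ep_success"}[table]
        kind = "cohens_d" if flavor == "categorical" else "partial_r"
        pred = mj.dropna(subset=[col])
        if flavor == "categorical":
            pred = pred.copy()
            pred[col] = pred[col].astype(float)
        n_by = pred.groupby(col)["male_id"].nunique() if flavor == "categorical" else None
        n1, n2 = (int(n_by.iloc[0]), int(n_by.iloc[1])) if n_by is not None and len(n_by) == 2 else (None, None)
        for trait, tr in TRAIT_RESPONSES.items():
            _trill_model(tname, trait, tr, col, pred, battery, kind, n1, n2)
        # male-year quality responses
        myp = my.dropna(subset=[col]).copy()
        myp[col] = myp[col].astype(float)
        for quality in QUALITY_MEASURES:
            if quality not in myp or myp[quality].dropna().nunique() < 2:
                continue
            sub = myp.dropna(subset=[quality])
            if sub[col].nunique() < 2:
                continue
            fixed = [col] + (["C(year)"] if sub.year.nunique() > 1 else [])
            family = "binomial" if quality in CATEGORICAL_QUALITY else "gaussian"
            spec = ModelSpec(response=quality, fixed=fixed, group="male_id", family=family)
            try:
                res = tgstats.fit_mixed(spec, sub)
                est = res.term(col)
            except Exception as err:  # singular/degenerate male-year designs
                log.warning("model %s ~ %s failed: %s", quality, col, err)
                continue
            nb = sub.groupby(col)["male_id"].nunique() if flavor == "categorical" else None
            q1, q2 = (int(nb.iloc[0]), int(nb.iloc[1])) if nb is not None and len(nb) == 2 else (None, None)
            battery.append(
                _battery_row(tname, quality, col, res, est,
                             "cohens_d" if flavor == "categorical" else "partial_r", q1, q2)
            )

    # ---- reproductive success ----------------------------------------
    rs = mj.dropna(subset=["annual_rs"])
    for trait, tr in TRAIT_RESPONSES.items():
        _trill_model("reproductive_success", trait, tr, "annual_rs", rs, battery, "partial_r")
    rs_my = my.dropna(subset=["annual_rs"])
    rs_preds = QUALITY_MEASURES + ["polygynous", "wp_proportion", "ep_success"]
    for predv in rs_preds:
        if predv not in rs_my or rs_my[predv].dropna().nunique() < 2:
            continue
        sub = rs_my.dropna(subset=[predv]).copy()
        categorical = predv in CATEGORICAL_QUALITY or predv in ("polygynous", "ep_success")
        if categorical:
            sub[predv] = sub[predv].astype(float)
        fixed = [predv] + (["C(year)"] if sub.year.nunique() > 1 else [])
        spec = ModelSpec(response="rs_t", fixed=fixed, group="male_id")
        try:
            res = tgstats.fit_mixed(spec, sub)
            est = res.term(predv)
        except Exception as err:
            log.warning("model rs ~ %s failed: %s", predv, err)
            continue
        nb = sub.groupby(predv)["male_id"].nunique() if categorical else None
        q1, q2 = (int(nb.iloc[0]), int(nb.iloc[1])) if nb is not None and len(nb) == 2 else (None, None)
        battery.append(
            _battery_row("reproductive_success", "annual_rs", predv, res, est,
                         "cohens_d" if categorical else "partial_r", q1, q2)
        )

    out = pd.DataFrame(battery)
    if out.empty:
        return out
    bad = ~np.isfinite(out.p)
    if bad.any():
        log.warning("dropping %d degenerate battery rows (non-finite p): %s",
                    int(bad.sum()),
                    out.loc[bad, ["table", "response", "predictor"]].to_dict("records"))
        out = out[~bad].reset_index(drop=True)
    fam = out.table.map(
        lambda t: "mating" if t in ("polygyny", "wp_success", "ep_success") else t
    )
    fdr = tgstats.bh_fdr(out.p.fillna(1.0), families=fam, q=fdr_q)
    out["family_id"] = fam.to_numpy()
    out["p_adjusted"] = fdr.p_adjusted.to_numpy()
    out["significant_fdr"] = fdr.reject.to_numpy()
    return out


def paired_epwp_tables(
    trills: pd.DataFrame,
    covariates: pd.DataFrame,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Paired comparisons of extra-pair sires vs. the males they cuckolded:
    mixed models for trill traits, paired t-tests for scalar quality."""
    ep = calls[(calls.status == "EP") & (calls.assigned_sire != "")]
    pairs = (
        ep[["year", "social_father_id", "assigned_sire"]]
        .drop_duplicates()
        .rename(columns={"social_father_id": "wp_male", "assigned_sire": "ep_male"})
    )
    pairs = pairs[pairs.wp_male != pairs.ep_male].reset_index(drop=True)
    rows = []
    if pairs.empty:
        return pd.DataFrame(rows)
    # trill-level paired mixed models
    frames = []
    for i, pr in pairs.iterrows():
        for role, mid in (("WP", pr.wp_male), ("EP", pr.ep_male)):
            sub = trills[(trills.male_id == mid) & (trills.year == pr.year)].copy()
            sub["role"] = role
            sub["pair_id"] = f"P{i:03d}"
            frames.append(sub)
    paired_trills = pd.concat(frames, ignore_index=True)
    for trait, tr in TRAIT_RESPONSES.items():
        data = paired_trills.dropna(subset=[trait])
        try:
            res = tgstats.paired_role_model(
                data, trait, "role", "male_id", "pair_id",
                extra_fixed=_acoustic_terms(data), transform_name=tr,
            )
            est = res.term("role")
            esv = tgstats.effect_partial_r(float(est.stat), float(est.df)) if np.isfinite(est.df) else None
            lsm = data.groupby("role")[trait].mean()
            rows.append(
                {
                    "trait": trait,
                    "n_pairs": pairs.shape[0],
                    "mean_wp": lsm.get("WP", np.nan),
                    "mean_ep": lsm.get("EP", np.nan),
                    "estimate": est.estimate,
                    "stat": est.stat,
                    "df": est.df,
                    "p": est.p,
                    "effect_size": esv.value if esv else np.nan,
                    "effect_ci_low": esv.ci_low if esv else np.nan,
                    "effect_ci_high": esv.ci_high if esv else np.nan,
                    "method": "mixed_role_model",
                }
            )
        except Exception as err:
            log.warning("paired trill model for %s failed: %s", trait, err)
    # scalar quality: paired t-tests on per-pair male-year values
    cov = covariates.set_index(["male_id", "year"])
    for quality in QUALITY_MEASURES:
        if quality not in covariates.columns or quality in CATEGORICAL_QUALITY:
            continue
        wp_v, ep_v = [], []
        for _, pr in pairs.iterrows():
            try:
                a = cov.loc[(pr.wp_male, pr.year), quality]
                b = cov.loc[(pr.ep_male, pr.year), quality]
            except KeyError:
                continue
            if pd.notna(a) and pd.notna(b):
                wp_v.append(float(a))
                ep_v.append(float(b))
        if len(wp_v) < 3:
            continue
        res = tgstats.paired_t(wp_v, ep_v)
        rows.append(
            {
                "trait": quality,
                "n_pairs": len(wp_v),
                "mean_wp": float(np.mean(wp_v)),
                "mean_ep": float(np.mean(ep_v)),
                "estimate": res["mean_diff"],
                "stat": res["t"],
                "df": res["df"],
                "p": res["p"],
                "effect_size": res["cohens_d"],
                "effect_ci_low": np.nan,
                "effect_ci_high": np.nan,
                "method": "paired_t",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------


def run_study(config: RunConfig) -> ResultBundle:
    """Simulate, measure, classify, and analyse one full study."""
    t0 = time.time()
    bundle = synth.simulate_population(config.population)
    log.info("simulated %d male-years, %d trills, %d offspring",
             len(bundle.male_years), len(bundle.trills),
             bundle.ground_truth["n_offspring"])

    measures = measure_bundle(bundle, audio=config.audio)
    limit = perf.upper_bound_regression(
        measures.rate, measures.bandwidth, bin_width=config.bin_width
    )
    measures = measures.copy()
    measures["deviation"] = perf.vocal_deviation(measures.rate, measures.bandwidth, limit)
    measures["consistency_t"] = perf.consistency_transform(
        measures.consistency.to_numpy()
    )
    log.info("measured %d trills; fitted limit slope=%.2f intercept=%.0f",
             len(measures), limit.slope, limit.intercept)

    calls = pat.classify_all(bundle.genotypes, bundle.nests)
    success = pat.male_year_success(calls, bundle.nests)
    locus_summary = pat.locus_summaries(bundle.genotypes)
    n_ep = int((calls.status == "EP").sum())
    log.info("classified %d offspring: %d EP (%.1f%%)", len(calls), n_ep,
             100.0 * n_ep / max(len(calls), 1))

    covariates = phen.male_year_covariates(bundle.phenotype, bundle.behavior)
    covariates["age_asy"] = covariates.age.map({"ASY": 1.0, "SY": 0.0, "": np.nan})
    covariates["flights_t"] = tgstats.transform("pow_0.55", covariates.flights.fillna(np.nan))
    covariates["time_close_t"] = tgstats.transform(
        "arcsine_sqrt", covariates.time_close.clip(0, 1)
    )
    covariates["hl_ratio_t"] = np.log(covariates.hl_ratio)

    # repeatability of both traits, covariate-adjusted
    rep_rows = []
    for trait, tr in TRAIT_RESPONSES.items():
        rep = tgstats.repeatability(
            measures.dropna(subset=[trait]),
            trait,
            _acoustic_terms(measures),
            "male_id",
            transform_name=tr,
        )
        rep_rows.append(
            {"trait": trait, "r": rep.r, "sigma2_between": rep.sigma2_between,
             "sigma2_within": rep.sigma2_within, "lrt": rep.lrt, "p": rep.p,
             "n_obs": rep.n_obs, "n_males": rep.n_groups}
        )
    repeat_df = pd.DataFrame(rep_rows)

    # between/within-male association: deviation as a function of consistency
    meas_c = measures.copy()
    meas_c["consistency_t"] = perf.consistency_transform(meas_c.consistency.to_numpy())
    dec = tgstats.within_between_decompose(
        meas_c,
        response="deviation",
        covariate="consistency_t",
        group_keys=["male_id", "trill_type", "year"],
        group="male_id",
        extra_fixed=_acoustic_terms(meas_c),
    )
    dec_df = pd.DataFrame(
        [
            {"effect": "between_male", "estimate": dec.beta_between, "se": dec.se_between,
             "stat": dec.t_between, "df": dec.df_between, "p": dec.p_between},
            {"effect": "within_male", "estimate": dec.beta_within, "se": dec.se_within,
             "stat": dec.t_within, "df": dec.df_within, "p": dec.p_within},
        ]
    )

    battery = run_battery(measures, covariates, success, fdr_q=config.fdr_q)
    paired = paired_epwp_tables(measures, covariates, calls)

    # ground-truth recovery diagnostics
    truth = bundle.ground_truth
    ep_true = truth["n_ep_offspring"] / max(truth["n_offspring"], 1)
    calls_res = calls[calls.status != "unresolved"]
    recovery = {
        "limit_slope_true": truth["limit_slope"],
        "limit_slope_est": limit.slope,
        "limit_intercept_true": truth["limit_intercept"],
        "limit_intercept_est": limit.intercept,
        "ep_rate_true": ep_true,
        "ep_rate_est": float((calls_res.status == "EP").mean()),
        "repeatability_deviation_true": truth["repeatability_deviation"],
        "repeatability_deviation_est": float(repeat_df.loc[repeat_df.trait == "deviation", "r"].iloc[0]),
        "repeatability_consistency_true": truth["repeatability_consistency"],
        "repeatability_consistency_est": float(repeat_df.loc[repeat_df.trait == "consistency", "r"].iloc[0]),
        "runtime_s": time.time() - t0,
    }
    truth_df = pd.DataFrame(truth["offspring"])
    if len(truth_df):
        merged = truth_df.merge(calls, on="offspring_id", how="inner")
        resolved = merged[merged.status != "unresolved"]
        recovery["ep_call_accuracy"] = float(
            (resolved.is_ep == (resolved.status == "EP")).mean()
        )
        ep_m = resolved[resolved.is_ep & (resolved.status == "EP")]
        if len(ep_m):
            recovery["ep_sire_recovery"] = float(
                (ep_m.assigned_sire == ep_m.true_sire).mean()
            )
    log.info("battery: %d tests, %d FDR-significant", len(battery),
             int(battery.significant_fdr.sum()) if len(battery) else 0)

    result = ResultBundle(
        config=config,
        bundle=bundle,
        measures=measures,
        limit=limit,
        calls=calls,
        success=success,
        covariates=covariates,
        locus_summary=locus_summary,
        repeatability=repeat_df,
        decomposition=dec_df,
        battery=battery,
        paired=paired,
        recovery=recovery,
    )
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result


def make_report(result: ResultBundle) -> str:
    """Human-readable run summary: counts, fitted limit, repeatabilities,
    significant associations, recovery diagnostics, and male-year least-
    squares-style trait means against reproductive success."""
    lines = []
    r = result
    lines.append("=== trillgauge study report ===")
    lines.append(
        f"trills measured: {len(r.measures)} across "
        f"{r.measures.male_id.nunique()} males / {len(r.bundle.male_years)} male-years"
    )
    lines.append(
        f"performance limit: bandwidth = {r.limit.slope:.2f} * rate + "
        f"{r.limit.intercept:.0f} Hz ({r.limit.n_bins} bins of {r.limit.bin_width} syll/s)"
    )
    dev = r.measures.deviation
    lines.append(f"vocal deviation: mean {dev.mean():.2f}, sd {dev.std():.2f}")
    cons = r.measures.consistency
    lines.append(f"trill consistency: mean {cons.mean():.3f}, sd {cons.std():.3f}")
    for _, row in r.repeatability.iterrows():
        lines.append(
            f"repeatability[{row.trait}]: r = {row.r:.3f} (LRT = {row.lrt:.1f}, p = {row.p:.2g})"
        )
    for _, row in r.decomposition.iterrows():
        lines.append(
            f"deviation ~ consistency ({row.effect}): {row.estimate:.3f} +/- {row.se:.3f},"
            f" t = {row.stat:.2f}, p = {row.p:.2g}"
        )
    res = r.calls[r.calls.status != "unresolved"]
    n_ep = int((res.status == "EP").sum())
    lines.append(
        f"paternity: {n_ep}/{len(res)} offspring EP ({100 * n_ep / max(len(res), 1):.1f}%)"
    )
    if len(r.battery) == 0:
        lines.append("statistical battery: zero models run")
    else:
        sig = r.battery[r.battery.significant_fdr]
        lines.append(
            f"statistical battery: {len(r.battery)} tests, {len(sig)} significant after FDR"
        )
        song_tables = {"quality_vs_trills", "polygyny", "wp_success", "ep_success",
                       "reproductive_success"}
        song_sig = sig[sig.table.isin(song_tables) & sig.response.isin(TRAIT_RESPONSES)]
        if song_sig.empty:
            lines.append("no significant song-success associations after FDR")
        else:
            for _, row in song_sig.iterrows():
                lines.append(
                    f"  {row.table}: {row.response} ~ {row.predictor} "
                    f"estimate {row.estimate:.3g} (p_adj = {row.p_adjusted:.3g})"
                )
    # male-year trait means vs reproductive success (scatter summary)
    mj = r.measures.merge(r.success, on=["male_id", "year"], how="inner")
    if len(mj) and mj.annual_rs.notna().any():
        means = mj.groupby(["male_id", "year"]).agg(
            deviation=("deviation", "mean"),
            consistency=("consistency", "mean"),
            annual_rs=("annual_rs", "first"),
        )
        for trait in ("deviation", "consistency"):
            ok = means[[trait, "annual_rs"]].dropna()
            if len(ok) > 2 and ok[trait].std() > 0 and ok.annual_rs.std() > 0:
                rho = float(np.corrcoef(ok[trait], ok.annual_rs)[0, 1])
                lines.append(
                    f"male-year mean {trait} vs annual RS: r = {rho:.3f} (n = {len(ok)})"
                )
    for k in sorted(r.recovery):
        lines.append(f"recovery {k}: {r.recovery[k]:.4g}" if isinstance(r.recovery[k], float)
                     else f"recovery {k}: {r.recovery[k]}")
    return "\n".join(lines) + "\n"
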