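"""End-to-end orchestration: bundle -> preprocessing -> SpTA muscle fields
-> synergies -> matching -> modifications -> rate correlations, with
deterministic text outputs.

Across-condition comparisons run only for units recorded (with enough
spikes) in both conditions; SST is the source condition throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import matching, modifications, preprocess, rate_correlation, spta
from . import synergies as syn
from .io_core import (
    CONDITIONS, EMGRecording, PipelineConfig, SpikeTrain, Trial, read_dataset,
)

STAGE_ORDER = ("preprocess", "spta", "synergies", "cluster", "match",
               "modify", "correlate")


@dataclass
class PipelineResults:
    config: PipelineConfig
    report: preprocess.PreprocessReport | None = None
    profiles: list[spta.SpTAProfile] = field(default_factory=list)
    fields: dict = field(default_factory=dict)       # (unit, cond) -> MuscleField
    synergy_sets: dict = field(default_factory=dict)  # cond -> SynergySet
    sample_idx: dict = field(default_factory=dict)    # cond -> np.ndarray
    matches: dict = field(default_factory=dict)       # cond -> MatchResult
    assignments: dict = field(default_factory=dict)   # "A->B" -> Assignment
    consistency: dict = field(default_factory=dict)
    cluster: matching.ClusterResult | None = None
    modification_results: list = field(default_factory=list)
    prevalence: dict = field(default_factory=dict)
    rate_profiles: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    pooled: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _condition_spike_times(
    spikes: SpikeTrain, trials: list[Trial], condition: str
) -> np.ndarray:
    """Spikes assigned to a condition by the trial block they fall in
    (each spike belongs to the most recent trial onset)."""
    ons = np.array([tr.stim_on for tr in trials])
    conds = np.array([tr.condition for tr in trials])
    idx = np.clip(np.searchsorted(ons, spikes.times) - 1, 0, len(trials) - 1)
    return spikes.times[conds[idx] == condition]


def run(
    dataset_dir: str | Path,
    seed: int = 0,
    config: PipelineConfig | None = None,
    upto: str = "correlate",
) -> PipelineResults:
    """Run the pipeline on a dataset bundle up to the requested stage."""
    rec, spikes, trials, bundle_cfg = read_dataset(dataset_dir)
    cfg = config or bundle_cfg
    res = PipelineResults(config=cfg)
    stop = STAGE_ORDER.index(upto)

    proc, res.report = preprocess.preprocess_pipeline(rec, cfg)
    if stop < STAGE_ORDER.index("spta"):
        return res

    conditions = [c for c in CONDITIONS
                  if any(tr.condition == c for tr in trials)]
    for st in spikes:
        for cond in conditions:
            t = _condition_spike_times(st, trials, cond)
            try:
                profs, fld = spta.analyze_unit(st, proc, cond, cfg, times=t)
            except spta.SpTAError as e:
                res.notes.append(f"{st.unit_id}/{cond}: {e}")
                continue
            res.profiles.extend(profs)
            res.fields[(st.unit_id, cond)] = fld
    if stop < STAGE_ORDER.index("synergies"):
        return res

    for cond in conditions:
        ss, idx = syn.extract_condition(proc, trials, cond, cfg, seed=seed)
        res.synergy_sets[cond] = ss
        res.sample_idx[cond] = idx

    if stop >= STAGE_ORDER.index("cluster"):
        W_sst = res.synergy_sets.get("SST")
        if W_sst is not None and W_sst.W.shape[1] >= 3:
            res.cluster = matching.cluster_synergies(
                W_sst.W, cfg.k_range, seed=seed
            )
        else:
            res.notes.append("clustering skipped: fewer than 3 SST synergies")

    if stop >= STAGE_ORDER.index("match"):
        for cond in conditions:
            flds = [res.fields[k] for k in sorted(res.fields)
                    if k[1] == cond and res.fields[k].valid]
            if flds:
                res.matches[cond] = matching.preferred_pairs(
                    flds, res.synergy_sets[cond]
                )
        for tgt in ("SSAT", "CoST"):
            if "SST" in res.synergy_sets and tgt in res.synergy_sets:
                a = matching.match_across_conditions(
                    res.synergy_sets["SST"].W, res.synergy_sets[tgt].W
                )
                res.assignments[f"SST->{tgt}"] = a
                res.consistency[f"SST->{tgt}"] = matching.consistency_rate(
                    a, cfg.consistency_sp
                )

    if stop >= STAGE_ORDER.index("modify"):
        src = res.matches.get("SST")
        for tgt in ("SSAT", "CoST"):
            m_tgt = res.matches.get(tgt)
            if src is None or m_tgt is None:
                continue
            for uid in src.unit_ids:
                if uid not in m_tgt.preferred_synergy:
                    continue
                i_src = src.preferred_synergy[uid]
                i_tgt = m_tgt.preferred_synergy[uid]
                res.modification_results.append(
                    modifications.classify_modification(
                        uid,
                        res.synergy_sets["SST"].W[:, i_src],
                        res.synergy_sets[tgt].W[:, i_tgt],
                        res.synergy_sets["SST"].W,
                        i_src,
                        condition_pair=f"SST->{tgt}",
                        config=cfg,
                    )
                )
        if res.modification_results:
            res.prevalence = modifications.prevalence_table(
                res.modification_results
            )

    if stop >= STAGE_ORDER.index("correlate"):
        cond = "SST"
        if cond in res.synergy_sets and cond in res.matches:
            ss = res.synergy_sets[cond]
            amps, loci = syn.coefficient_amplitudes(
                ss.C, res.sample_idx[cond], proc, trials, cond, cfg
            )
            pooled_x, pooled_corres, pooled_prefer = [], [], []
            for st in spikes:
                uid = st.unit_id
                if uid not in res.matches[cond].preferred_synergy:
                    continue
                rp = rate_correlation.firing_rate_by_locus(
                    st, trials, cond, cfg
                )
                res.rate_profiles[uid] = rp
                try:
                    cr = rate_correlation.correlate(
                        rp, amps, res.matches[cond].preferred_synergy[uid]
                    )
                except rate_correlation.CorrelationError as e:
                    res.notes.append(f"correlate {uid}: {e}")
                    continue
                res.correlations[uid] = cr
                pooled_x.extend(rp.rates.tolist())
                pooled_corres.extend(
                    amps[res.matches[cond].preferred_synergy[uid]].tolist()
                )
                pooled_prefer.extend(amps[cr.c_prefer_index].tolist())
            if len(pooled_x) >= 3:
                for name, ys in (("C_corres", pooled_corres),
                                 ("C_prefer", pooled_prefer)):
                    slope, r2, p = rate_correlation.pooled_regression(
                        np.array(pooled_x), np.array(ys)
                    )
                    res.pooled[name] = {
                        "slope": slope, "Rsq": r2, "p": p,
                        "n_points": len(pooled_x),
                    }
    return res


# ---------------------------------------------------------------------------
# deterministic text output

def _df_write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _json_write(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def write_results(
    res: PipelineResults, out_dir: str | Path,
    stages: set[str] | None = None,
) -> None:
    """Write the requested stages' outputs as TSV/JSON (byte-deterministic
    for identical results)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(stages or STAGE_ORDER)

    if "preprocess" in stages and res.report is not None:
        _json_write(asdict(res.report), out / "preprocess_report.json")

    if "spta" in stages and res.profiles:
        rows = []
        for p in res.profiles:
            rows.append({
                "unit_id": p.unit_id, "muscle": p.muscle,
                "n_spikes": p.n_spikes, "n_dropped": p.n_dropped,
                "baseline_mean": p.baseline_mean, "baseline_sd": p.baseline_sd,
                "peak_latency_ms": p.peak_latency_ms,
                "onset_latency_ms": p.onset_latency_ms,
                "pwhm_ms": p.pwhm_ms, "increment_pct": p.increment_pct,
                "significant": p.significant, "effect_type": p.effect_type,
            })
        _df_write(pd.DataFrame(rows), out / "spta_profiles.tsv")
        rows = []
        for (uid, cond) in sorted(res.fields):
            f = res.fields[(uid, cond)]
            for m, v, vn in zip(f.muscles, f.values, f.values_norm):
                rows.append({"unit_id": uid, "condition": cond, "muscle": m,
                             "increment_pct": v, "weight_norm": vn,
                             "valid": f.valid})
        _df_write(pd.DataFrame(rows), out / "muscle_fields.tsv")

    if "synergies" in stages:
        model_order = {}
        for cond in sorted(res.synergy_sets):
            ss = res.synergy_sets[cond]
            df = pd.DataFrame(
                ss.W, columns=[f"synergy_{i + 1}" for i in range(ss.N)]
            )
            df.insert(0, "muscle", list(ss.muscles))
            _df_write(df, out / f"synergies_{cond}.tsv")
            _df_write(
                pd.DataFrame(
                    ss.C, columns=[f"C_{i + 1}" for i in range(ss.N)]
                ),
                out / f"coefficients_{cond}.tsv",
            )
            model_order[cond] = {
                "N": ss.N, "R2": ss.R2,
                "r2_by_order": {str(k): v for k, v in ss.r2_by_order.items()},
            }
        _json_write(model_order, out / "model_order.json")

    if "cluster" in stages and res.cluster is not None:
        _json_write(
            {
                "k_selected": res.cluster.k_selected,
                "labels": res.cluster.labels.tolist(),
                "silhouette_by_k": {str(k): v for k, v in
                                    res.cluster.silhouette_by_k.items()},
            },
            out / "clusters.json",
        )

    if "match" in stages:
        rows = []
        for cond in sorted(res.matches):
            m = res.matches[cond]
            for uid in m.unit_ids:
                rows.append({
                    "unit_id": uid, "condition": cond,
                    "preferred_synergy": m.preferred_synergy[uid] + 1,
                    "preferred_sp": m.preferred_sp[uid],
                })
        if rows:
            _df_write(pd.DataFrame(rows), out / "preferred_pairs.tsv")
        assign = {}
        for key in sorted(res.assignments):
            a = res.assignments[key]
            assign[key] = {
                "pairs": [[int(r) + 1, int(c) + 1] for r, c in a.pairs],
                "pair_sp": a.pair_sp, "mean_sp": a.mean_sp,
                "consistency_rate": res.consistency.get(key),
            }
        if assign:
            _json_write(assign, out / "across_condition_matches.json")

    if "modify" in stages and res.modification_results:
        rows = [{
            "unit_id": r.unit_id, "condition_pair": r.condition_pair,
            "form": r.form,
            "coefficients": ",".join(f"{c:.6g}" for c in r.nnls_coefficients),
            "reconstruction_sp": r.reconstruction_sp,
            "pairwise_sp": r.pairwise_sp,
        } for r in res.modification_results]
        _df_write(pd.DataFrame(rows), out / "modifications.tsv")
        _json_write(res.prevalence, out / "prevalence.json")

    if "correlate" in stages and res.correlations:
        rows = []
        for uid in sorted(res.correlations):
            cr = res.correlations[uid]
            rows.append({
                "unit_id": uid,
                "r_by_synergy": ",".join(f"{r:.6g}" for r in cr.r_by_synergy),
                "C_corres_r": cr.c_corres_r,
                "C_prefer_index": cr.c_prefer_index + 1,
                "C_prefer_r": cr.c_prefer_r,
            })
        _df_write(pd.DataFrame(rows), out / "correlations.tsv")
        rate_rows = []
        for uid in sorted(res.rate_profiles):
            rp = res.rate_profiles[uid]
            for locus, r in zip(rp.loci, rp.rates):
                rate_rows.append({"unit_id": uid, "locus_um": locus,
                                  "rate_hz": r})
        _df_write(pd.DataFrame(rate_rows), out / "rate_profiles.tsv")
        if res.pooled:
            _json_write(res.pooled, out / "pooled_regression.json")

    if res.notes:
        _json_write({"notes": sorted(res.notes)}, out / "notes.json")


def run_all(
    dataset_dir: str | Path, out_dir: str | Path, seed: int = 0,
    config: PipelineConfig | None = None,
) -> PipelineResults:
    """Full pipeline with all outputs written to ``out_dir``."""
    res = run(dataset_dir, seed=seed, config=config, upto="correlate")
    write_results(res, out_dir)
    return res
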