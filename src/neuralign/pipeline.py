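"""End-to-end orchestration: simulate/load → preprocess → MCCA/ISC → stats.

``run_pipeline`` executes, for every group × band × timeslot cell:
band-pass filtering, pause removal, timeslot split, standardization,
3-fold cross-validated MCCA with test-ISC component selection, and a
circular-bootstrap significance test; then, on the primary band, the
subject-level ISC trajectories feed a mixed (group × time) ANOVA with
per-group repeated-measures follow-ups, and the designated group's
individual end-slot ISCs are correlated (BH-FDR corrected) with the nine
questionnaire T2−T1 changes. Agreement trajectories get the same ANOVA
treatment, and the agreement end−beginning change is correlated with the
questionnaire changes.

All randomness flows from the single config seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream_seed
from .behavior import (
    BehaviorTable,
    DELTA_MEASURES,
    agreement_by_timeslot,
    composite_scores,
    correlate_with_fdr,
    map_statements_to_slots,
    mixed_anova,
    rm_anova,
)
from .isc import ISCResult, bootstrap_isc, crossval_isc
from .preprocess import BANDS, SLOT_NAMES, preprocess_group
from .simulate import SimulationConfig, generate_behavior, generate_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, reachable from one YAML/JSON mapping."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    load_paths: list[str] | None = None  # HDF5 group files; None → simulate
    behavior_path: str | None = None  # behavior CSV when loading
    bands: tuple[str, ...] = ("delta", "theta", "alpha")
    primary_band: str = "delta"
    n_timeslots: int = 3
    n_folds: int = 3
    n_components: int = 10
    gamma: float = 0.05
    pca_var: float | None = None
    n_bootstrap: int = 1000
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "neuralign_out"

    def __post_init__(self) -> None:
        unknown = [b for b in self.bands if b not in BANDS]
        if unknown:
            raise ValueError(f"unknown bands {unknown}; choose from {sorted(BANDS)}")
        if self.primary_band not in self.bands:
            raise ValueError("primary_band must be among the analyzed bands")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")
        # keep the simulation's seed and slot count in lockstep with the run
        self.simulation = dataclasses.replace(
            self.simulation, seed=substream_seed(self.seed, "simulate"),
            n_timeslots=self.n_timeslots,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for key in ("group_sizes", "statement_duration_range", "source_band",
                        "coupling_range", "agreement_trend", "agreement_baseline"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "shared_snr_schedule" in sim:
                sim["shared_snr_schedule"] = tuple(tuple(r) for r in sim["shared_snr_schedule"])
            sim = SimulationConfig(**sim)
        for key in ("bands",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


@dataclass
class RunReport:
    """Paths to the result tables plus the machine-readable summary."""

    summary: dict
    summary_path: Path
    isc_table_path: Path
    individual_isc_path: Path
    anova_path: Path
    correlation_path: Path


def _anova_rows(results, context: dict) -> list[dict]:
    rows = []
    for r in results:
        if np.isnan(r.F):
            continue
        rows.append({**context, "effect": r.effect, "F": round(r.F, 6),
                     "df_num": r.df[0], "df_den": r.df[1], "p": round(r.p, 8)})
    return rows


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; returns a report with all output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=False,
    )

    # ---- stage: data -------------------------------------------------------
    if config.load_paths:
        from .io import load_dataset

        datasets = [load_dataset(p) for p in config.load_paths]
        behavior = BehaviorTable.from_csv(config.behavior_path) if config.behavior_path else None
        ground_truth = None
        events = datasets[0].events
        logger.info("loaded %d group dataset(s)", len(datasets))
    else:
        try:
            datasets, ground_truth, events = generate_dataset(config.simulation)
            behavior = generate_behavior(
                ground_truth, config.simulation, substream_seed(config.seed, "behavior")
            )
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage simulate failed: {err}") from err
        logger.info("simulated %d groups", len(datasets))

    # ---- stage: preprocess + MCCA/ISC + bootstrap --------------------------
    isc_rows, indiv_rows, boot_summaries = [], [], {}
    isc_results: dict[tuple[str, str, str], ISCResult] = {}
    for ds in datasets:
        for band_name in config.bands:
            try:
                slots = preprocess_group(ds.recordings, BANDS[band_name], config.n_timeslots)
            except Exception as err:  # noqa: BLE001
                raise RuntimeError(
                    f"stage preprocess failed for group={ds.group} band={band_name}: {err}"
                ) from err
            for s, slot in enumerate(slots):
                try:
                    res = crossval_isc(
                        slot.data, K=config.n_components, n_folds=config.n_folds,
                        gamma=config.gamma, pca_var=config.pca_var,
                    )
                    boot = bootstrap_isc(
                        res.test_series, B=config.n_bootstrap,
                        seed=substream_seed(config.seed, f"boot/{ds.group}/{band_name}/{s}"),
                    )
                except Exception as err:  # noqa: BLE001
                    raise RuntimeError(
                        f"stage isc failed for group={ds.group} band={band_name} "
                        f"slot={slot.slot}: {err}"
                    ) from err
                isc_results[(ds.group, band_name, slot.slot)] = res
                boot_summaries[f"{ds.group}/{band_name}/{slot.slot}"] = {
                    "observed_isc": round(boot.observed, 6),
                    "p_value": round(boot.p_value, 6),
                    "null_mean": round(float(boot.null_samples.mean()), 6),
                    "significant": bool(boot.p_value < config.alpha),
                }
                for f in range(config.n_folds):
                    for k in range(res.n_components):
                        isc_rows.append({
                            "group": ds.group, "band": band_name, "timeslot": slot.slot,
                            "fold": f, "component": k,
                            "train_isc": round(float(res.train_isc[f, k]), 6),
                            "test_isc": round(float(res.per_fold[f, k]), 6),
                        })
                for i in range(len(res.individual_isc)):
                    indiv_rows.append({
                        "group": ds.group, "band": band_name, "timeslot": slot.slot,
                        "subject": i,
                        "individual_isc": round(float(res.individual_isc[i]), 6),
                        "individual_isc_one_vs_rest": round(float(res.individual_isc_ovr[i]), 6),
                    })
                logger.info("ISC %s/%s/%s: group ISC %.4f (comp %d), p=%.4f",
                            ds.group, band_name, slot.slot, res.group_isc,
                            res.selected_component, boot.p_value)

    # ---- stage: group-level stats on ISC trajectories ----------------------
    slot_names = SLOT_NAMES if config.n_timeslots == 3 else tuple(
        f"slot{s}" for s in range(config.n_timeslots)
    )
    anova_rows, neural_anova = [], {}
    for band_name in config.bands:
        traj, labels = [], []
        for ds in datasets:
            block = np.column_stack([
                isc_results[(ds.group, band_name, sn)].individual_isc for sn in slot_names
            ])
            traj.append(block)
            labels += [ds.group] * block.shape[0]
        values = np.vstack(traj)
        try:
            mixed = mixed_anova(values, labels)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage stats (ISC ANOVA, band={band_name}) failed: {err}") from err
        anova_rows += _anova_rows(mixed, {"analysis": "isc", "band": band_name, "group": "all"})
        per_group = {}
        offset = 0
        for ds, block in zip(datasets, traj):
            r = rm_anova(block)
            anova_rows += _anova_rows([r], {"analysis": "isc", "band": band_name,
                                            "group": ds.group})
            per_group[ds.group] = {"F": round(r.F, 6), "df": list(r.df), "p": round(r.p, 8)}
        inter = next(r for r in mixed if r.effect == "group x time")
        neural_anova[band_name] = {
            "interaction": {"F": round(inter.F, 6), "df": list(inter.df),
                            "p": round(inter.p, 8), "significant": bool(inter.p < config.alpha)},
            "per_group_time_effect": per_group,
        }

    # ---- stage: behavior ---------------------------------------------------
    behavior_summary, corr_rows = {}, []
    if behavior is not None:
        slot_map = map_statements_to_slots(events, config.n_timeslots)
        ag = agreement_by_timeslot(behavior, slot_map, config.n_timeslots)
        ag_cols = [f"agreement_slot{s}" for s in range(config.n_timeslots)]
        mixed = mixed_anova(ag[ag_cols].to_numpy(), ag["group"])
        anova_rows += _anova_rows(mixed, {"analysis": "agreement", "band": "", "group": "all"})
        inter = next(r for r in mixed if r.effect == "group x time")
        per_group = {}
        for ds in datasets:
            sub = ag[ag["group"] == ds.group]
            r = rm_anova(sub[ag_cols].to_numpy())
            anova_rows += _anova_rows([r], {"analysis": "agreement", "band": "",
                                            "group": ds.group})
            per_group[ds.group] = {"F": round(r.F, 6), "df": list(r.df), "p": round(r.p, 8)}
        behavior_summary["agreement_anova"] = {
            "interaction": {"F": round(inter.F, 6), "df": list(inter.df),
                            "p": round(inter.p, 8)},
            "per_group_time_effect": per_group,
        }

        scores = composite_scores(behavior)
        target_group = config.simulation.group_names[config.simulation.behavior_group]
        mask = (scores["group"] == target_group).to_numpy()
        end_slot = slot_names[-1]
        x = isc_results[(target_group, config.primary_band, end_slot)].individual_isc
        deltas = scores.loc[mask, [f"{m}_delta" for m in DELTA_MEASURES]]
        deltas.columns = list(DELTA_MEASURES)
        reports = correlate_with_fdr(x, deltas)
        for rep in reports:
            corr_rows.append({"x": f"isc_{config.primary_band}_{end_slot}",
                              "measure": rep.measure, "R": round(rep.R, 6),
                              "p_raw": round(rep.p_raw, 8), "p_fdr": round(rep.p_fdr, 8),
                              "n": rep.n})
        behavior_summary["isc_behavior_correlations"] = {
            rep.measure: {"R": round(rep.R, 6), "p_fdr": round(rep.p_fdr, 8),
                          "significant": bool(rep.p_fdr < config.alpha)}
            for rep in reports
        }
        ag_diff = ag.loc[mask, "agreement_diff"].to_numpy()
        reports2 = correlate_with_fdr(ag_diff, deltas)
        for rep in reports2:
            corr_rows.append({"x": "agreement_diff", "measure": rep.measure,
                              "R": round(rep.R, 6), "p_raw": round(rep.p_raw, 8),
                              "p_fdr": round(rep.p_fdr, 8), "n": rep.n})
        behavior_summary["agreement_behavior_correlations"] = {
            rep.measure: {"R": round(rep.R, 6), "p_fdr": round(rep.p_fdr, 8),
                          "significant": bool(rep.p_fdr < config.alpha)}
            for rep in reports2
        }

    # ---- outputs -----------------------------------------------------------
    isc_path = out / "isc_by_fold.csv"
    pd.DataFrame(isc_rows).to_csv(isc_path, index=False)
    indiv_path = out / "individual_isc.csv"
    pd.DataFrame(indiv_rows).to_csv(indiv_path, index=False)
    anova_path = out / "anova.csv"
    pd.DataFrame(anova_rows).to_csv(anova_path, index=False)
    corr_path = out / "correlations.csv"
    pd.DataFrame(corr_rows).to_csv(corr_path, index=False)

    group_isc = {
        f"{g}/{b}/{s}": {
            "group_isc": round(res.group_isc, 6),
            "selected_component": res.selected_component,
        }
        for (g, b, s), res in isc_results.items()
    }
    summary = {
        "config": {
            "bands": list(config.bands), "primary_band": config.primary_band,
            "n_timeslots": config.n_timeslots, "n_folds": config.n_folds,
            "n_components": config.n_components, "gamma": config.gamma,
            "n_bootstrap": config.n_bootstrap, "alpha": config.alpha,
            "seed": config.seed,
            "group_sizes": list(config.simulation.group_sizes) if not config.load_paths else
            [ds.n_subjects for ds in datasets],
        },
        "group_isc": group_isc,
        "bootstrap": boot_summaries,
        "neural_anova": neural_anova,
        "behavior": behavior_summary,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete; summary at %s", summary_path)
    return RunReport(
        summary=summary, summary_path=summary_path, isc_table_path=isc_path,
        individual_isc_path=indiv_path, anova_path=anova_path, correlation_path=corr_path,
    )
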