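"""Trial-table serialization, configuration, and the end-to-end pipeline.

One tidy CSV schema (``design.SCHEDULE_COLUMNS``) is shared by the
scheduler, the synthetic observer, and real-data ingestion, so deposited
behavioural data can be analysed by mapping columns onto it.  The baseline
condition is stored as adaptor_deg = -999 on disk and in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import glmm, sequential
from .design import BASELINE, DesignSpec
from .observer import ObserverParams, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_trials", "write_trials", "run_pipeline",
           "ValidationError"]

REQUIRED_COLUMNS = ["participant", "session", "trial_index", "adaptor_deg",
                    "standard_deg", "offset_deg", "response"]

VALID_ADAPTORS = {0.0, 45.0, 90.0, 135.0, BASELINE}


class ValidationError(ValueError):
    """Trial-table validation failed; message itemizes the problems."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    participants: int = 8
    ppd: float = 75.5
    design: DesignSpec = field(default_factory=DesignSpec)
    observer: ObserverParams = field(default_factory=ObserverParams)
    n_perm: int = 1000
    alpha: float = 0.05
    seed_design: int = 1
    seed_simulation: int = 2
    seed_permutation: int = 3
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["observer"]["buildup_tau"] = (
            None if np.isinf(self.observer.buildup_tau)
            else self.observer.buildup_tau)
        d["observer"]["condition_bias"] = {
            f"{k[0]}|{k[1]}": v
            for k, v in self.observer.condition_bias.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            spec = dict(d["design"])
            if "offsets" in spec:
                spec["offsets"] = tuple(spec["offsets"])
            d["design"] = DesignSpec(**spec)
        if "observer" in d:
            obs = dict(d["observer"])
            if obs.get("buildup_tau") is None:
                obs["buildup_tau"] = np.inf
            if "condition_bias" in obs:
                obs["condition_bias"] = {
                    tuple(float(x) for x in k.split("|")): v
                    for k, v in obs["condition_bias"].items()}
            if "baseline_bias" in obs:
                obs["baseline_bias"] = {float(k): v
                                        for k, v in obs["baseline_bias"].items()}
            d["observer"] = ObserverParams(**obs)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (baseline sentinel kept as -999)."""
    out = trials.copy()
    out.to_csv(path, index=False, float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Checks the required columns, adaptor codes (0/45/90/135 or the -999
    baseline sentinel), and that offsets and standards are folded to their
    canonical ranges; raises :class:`ValidationError` listing every
    problem found.
    """
    df = pd.read_csv(path)
    problems = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    bad_adapt = sorted(set(df["adaptor_deg"].astype(float))
                       - VALID_ADAPTORS)
    if bad_adapt:
        problems.append(f"unknown adaptor codes: {bad_adapt}")
    spec_offsets = set(DesignSpec().offsets)
    doubled = {2 * o for o in spec_offsets}
    ok_offsets = spec_offsets | doubled
    bad_off = sorted(set(df["offset_deg"].astype(float)) - ok_offsets)
    if bad_off:
        problems.append(f"offsets outside the design: {bad_off}")
    bad_std = sorted(set(df["standard_deg"].astype(float))
                     - set(dz.STANDARD_SET))
    if bad_std:
        problems.append(f"standard orientations outside the design: {bad_std}")
    resp = df["response"].dropna()
    if not resp.isin([0, 1]).all():
        problems.append("responses must be 0/1 (or empty)")
    if problems:
        raise ValidationError("; ".join(problems))
    if "phase" not in df.columns:
        df["phase"] = "main"
    if "include_in_baseline" not in df.columns:
        df["include_in_baseline"] = df["adaptor_deg"] == BASELINE
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def quality_check_cohort(completed: pd.DataFrame, alpha: float = 0.05
                         ) -> tuple[pd.DataFrame, list]:
    """Run the baseline likelihood-ratio check on every participant.

    Returns the per-participant QC table and the list of passing
    participant ids; participants whose baseline responses are not better
    explained by a psychometric function than by chance are excluded from
    downstream analyses.
    """
    rows, keep = [], []
    for pid, grp in completed.groupby("participant"):
        base = grp.loc[(grp["adaptor_deg"] == BASELINE)
                       & grp["include_in_baseline"].astype(bool)]
        res = glmm.quality_check(base, alpha=alpha)
        rows.append({"participant": pid, "pass": res["pass"],
                     "p": res["p"], "statistic": res["statistic"]})
        if res["pass"]:
            keep.append(pid)
    return pd.DataFrame(rows), keep


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Design -> simulate -> quality check -> bias model -> sequential analysis.

    Writes every stage's table under the output directory plus a manifest
    recording seeds, stage outputs, file hashes and exclusion counts.
    Participants failing the baseline quality check are excluded before the
    bias model and sequential analysis.  Returns the manifest dict.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seeds": {"design": config.seed_design,
                          "simulation": config.seed_simulation,
                          "permutation": config.seed_permutation},
                "stages": {}}

    def record(stage, path, **extra):
        p = Path(path)
        if p.is_dir():
            digest = hashlib.sha256("".join(
                _sha256(f) for f in sorted(p.glob("*.csv"))).encode()
            ).hexdigest()
        else:
            digest = _sha256(p)
        manifest["stages"][stage] = {"path": str(p), "sha256": digest, **extra}

    pids = [f"p{i:02d}" for i in range(1, config.participants + 1)]
    schedule = dz.build_cohort_schedule(config.design, pids,
                                        config.seed_design)
    sched_path = out / "schedule.csv"
    write_trials(schedule, sched_path)
    record("make-design", sched_path, trials=len(schedule))

    completed, truth = simulate_cohort(schedule, config.observer,
                                       config.seed_simulation)
    resp_path = out / "responses.csv"
    write_trials(completed, resp_path)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth.to_dict("records"), indent=1))
    record("simulate", resp_path, trials=len(completed))

    qc, keep = quality_check_cohort(completed, alpha=config.alpha)
    qc_path = out / "quality_check.csv"
    qc.to_csv(qc_path, index=False)
    record("qc", qc_path, passed=len(keep),
           excluded=config.participants - len(keep))
    logger.info("quality check: %d/%d participants pass", len(keep),
                config.participants)
    analysed = completed.loc[completed["participant"].isin(keep)]
    if len(keep) < 2:
        raise RuntimeError(
            f"stage fit-bias: only {len(keep)} participants pass the "
            "quality check; multilevel fit needs >= 2")

    fit = glmm.fit_bias_model(analysed)
    biases = glmm.cell_bias_table(fit, subtract=True)
    bias_path = out / "biases.csv"
    biases.to_csv(bias_path, index=False)
    coef_path = out / "coefficients.json"
    coef_path.write_text(json.dumps(
        {"names": fit.names, "params": fit.params.tolist(),
         "loglik": fit.loglik}, indent=1))
    record("fit-bias", bias_path, cells=len(biases),
           loglik=fit.loglik, sigma_u=fit.sigma_u)

    results = sequential.sequential_analysis(
        analysed, n_perm=config.n_perm, seed=config.seed_permutation)
    seq_dir = out / "sequential"
    seq_dir.mkdir(exist_ok=True)
    n_flagged = 0
    for rel, res in results.items():
        tbl = sequential.result_table(res)
        tbl.to_csv(seq_dir / f"rel_standard_{rel:+.1f}.csv", index=False)
        n_flagged += int(res.flags.sum())
    record("seqperm", seq_dir, strata=len(results),
           flagged_trials=n_flagged)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
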