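"""End-to-end study orchestration: simulate, analyze, estimate, compare.

`run_study` drives the full synthetic replication: a 2x2 cohort is
simulated, each recording is reduced to a first-harmonic spectral
response, tuning curves are built per participant x condition and fed to
the heuristic (and optionally the ML) acuity estimator, and the
translucent-vs-opaque occlusion contrast is tested within each vision
level with paired permutation tests, bootstrap confidence intervals and a
Bonferroni factor of 2 for the two-family comparison.

All intermediate tables are plain CSV; the run log records seeds, the
package version and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conversion import ACUITY_CLIP_CEILING, DEFAULT_CONVERSION_FACTOR
from .heuristic import build_curve, estimate_acuity, flag_spurious
from .ml import make_training_corpus, predict, save_estimator, train
from .spectral import analyze_recording
from .stats import PairedDifferences, compare_conditions
from .synthetic import CONDITIONS, StimulusSet, generate_cohort


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class StudyConfig:
    """Every tunable of the synthetic study in one place.

    Analysis constants default to the study's printed values: 120-uV
    rejection threshold, single-test alpha 0.05, decimal-acuity clip
    ceiling 1.6, Bonferroni factor 2.
    """

    # cohort
    n_participants: int = 16
    effect: float = -0.06
    seed: int = 0
    degradation_delta: float = 1.06
    noise_sd: float | None = None  # None -> per-participant draw
    blink_rate: float | None = None
    peak_amplitude: float | None = None
    # stimulus
    check_sizes: tuple[float, ...] = (60.0, 30.0, 15.0, 7.5, 3.75, 1.875)
    reversal_rate: float = 8.0
    segment_length: float = 1.0
    n_segments: int = 80
    sampling_rate: float = 1000.0
    # spectral analysis
    rejection_threshold: float = 120.0
    alpha: float = 0.05
    k_neighbors: int = 2
    # acuity
    conversion_factor: float = DEFAULT_CONVERSION_FACTOR
    clip_ceiling: float = ACUITY_CLIP_CEILING
    auto_spurious: bool = True
    include_trailing_nonsig: bool = False
    # ML estimator
    train_ml: bool = True
    ml_corpus_size: int = 200
    ml_logmar_range: tuple[float, float] = (-0.2, 0.4)
    ml_noise_sd: float = 20.0
    ml_hidden: tuple[int, ...] = (32,)
    ml_margin: float = 0.1
    # statistics
    n_permutations: int = 100_000
    n_boot: int = 10_000
    ci_level: float = 0.95
    bonferroni_factor: int = 2

    def stimulus(self) -> StimulusSet:
        return StimulusSet(
            check_sizes=self.check_sizes,
            reversal_rate=self.reversal_rate,
            segment_length=self.segment_length,
            n_segments=self.n_segments,
            sampling_rate=self.sampling_rate,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        raw = json.loads(text)
        for key in ("check_sizes", "ml_logmar_range", "ml_hidden"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _derive_seed(base: int, offset: int) -> int:
    return (int(base) + 1_000_003 * offset) % (2**31)


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study; optionally persist the results bundle.

    Returns a dict with the ground-truth table, the spectral-response
    table, the per-condition acuity estimates (heuristic and ML), the
    condition-contrast comparisons and the run log. With ``out_dir`` each
    table is also written as CSV, plus ``run_log.json``, ``config.json``
    and the serialized ML model.
    """
    stimulus = config.stimulus()
    try:
        cohort = generate_cohort(
            config.n_participants,
            config.effect,
            config.seed,
            stimulus,
            degradation_delta=config.degradation_delta,
            noise_sd=config.noise_sd,
            blink_rate=config.blink_rate,
            peak_amplitude=config.peak_amplitude,
            conversion_factor=config.conversion_factor,
        )
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    spectral_rows: list[dict] = []
    estimate_rows: list[dict] = []
    curves: dict[tuple[str, str], object] = {}
    total_rejected = 0

    for participant in cohort.participants:
        for condition in CONDITIONS:
            responses = []
            for check in stimulus.check_sizes:
                rec = cohort.recording(participant, condition, check)
                try:
                    resp = analyze_recording(
                        rec,
                        threshold=config.rejection_threshold,
                        k_neighbors=config.k_neighbors,
                        alpha=config.alpha,
                    )
                except Exception as exc:
                    raise StageError(
                        "analyze",
                        f"{participant.participant_id}/{condition}/check {check:g}: {exc}",
                    ) from exc
                responses.append(resp)
                if resp is not None:
                    total_rejected += resp.n_segments_rejected
                    spectral_rows.append(
                        {
                            "participant": participant.participant_id,
                            "condition": condition,
                            "check_size": resp.check_size,
                            "spatial_frequency": resp.spatial_frequency,
                            "log_sf": resp.log_sf,
                            "amplitude_raw": resp.amplitude_raw,
                            "noise_amplitude": resp.noise_amplitude,
                            "amplitude_corrected": resp.amplitude_corrected,
                            "p_value": resp.p_value,
                            "significant": resp.significant,
                            "n_segments_kept": resp.n_segments_kept,
                            "n_segments_rejected": resp.n_segments_rejected,
                        }
                    )
            try:
                curve = build_curve(responses)
                if config.auto_spurious:
                    curve = flag_spurious(curve, "auto")
                est = estimate_acuity(
                    curve,
                    config.conversion_factor,
                    include_trailing_nonsig=config.include_trailing_nonsig,
                    clip_ceiling=config.clip_ceiling,
                )
            except Exception as exc:
                raise StageError(
                    "estimate", f"{participant.participant_id}/{condition}: {exc}"
                ) from exc
            curves[(participant.participant_id, condition)] = curve
            estimate_rows.append(
                {
                    "participant": participant.participant_id,
                    "condition": condition,
                    "method": "heuristic",
                    "status": est.status,
                    "sf_limit": est.sf_limit,
                    "decimal_acuity": est.decimal_acuity,
                    "logmar": est.logmar,
                    "clipped": est.clipped,
                    "fit_points": ";".join(str(i) for i in est.fit_points),
                    "reason": est.reason,
                }
            )

    estimator = None
    if config.train_ml:
        try:
            corpus = make_training_corpus(
                config.ml_corpus_size,
                seed=_derive_seed(config.seed, 1),
                logmar_range=config.ml_logmar_range,
                noise_sd=config.ml_noise_sd,
                stimulus=stimulus,
                conversion_factor=config.conversion_factor,
            )
            estimator = train(
                [(f, y) for _, f, y in corpus],
                seed=_derive_seed(config.seed, 2),
                hidden_layer_sizes=config.ml_hidden,
                margin=config.ml_margin,
            )
        except Exception as exc:
            raise StageError("train-ml", str(exc)) from exc
        for (pid, condition), curve in curves.items():
            pred = predict(estimator, curve)
            estimate_rows.append(
                {
                    "participant": pid,
                    "condition": condition,
                    "method": "ml",
                    "status": pred.status,
                    "sf_limit": None,
                    "decimal_acuity": None,
                    "logmar": pred.logmar,
                    "clipped": False,
                    "fit_points": "",
                    "reason": pred.reason,
                }
            )

    estimates = pd.DataFrame(estimate_rows).sort_values(
        ["method", "participant", "condition"], kind="stable"
    )
    comparisons = _compare_occlusion(estimates, config)

    run_log = {
        "package_version": _package_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "derived_seeds": {
            "ml_corpus": _derive_seed(config.seed, 1),
            "ml_train": _derive_seed(config.seed, 2),
            "stats": _derive_seed(config.seed, 3),
        },
        "n_participants": config.n_participants,
        "total_segments_rejected": int(total_rejected),
        "ml_trained": estimator is not None,
    }

    bundle = {
        "ground_truth": cohort.ground_truth,
        "spectral_responses": pd.DataFrame(spectral_rows),
        "estimates": estimates.reset_index(drop=True),
        "comparisons": comparisons,
        "run_log": run_log,
        "estimator": estimator,
        "cohort": cohort,
        "curves": curves,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("ground_truth", "spectral_responses", "estimates", "comparisons"):
            bundle[name].to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
        (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
        (out_dir / "config.json").write_text(config.to_json())
        if estimator is not None:
            save_estimator(estimator, out_dir / "ml_model.json")
    return bundle


def _compare_occlusion(estimates: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Translucent - opaque contrasts per method x vision level x statistic."""
    rows = []
    seed = _derive_seed(config.seed, 3)
    for method in estimates["method"].unique():
        for vision in ("normal", "degraded"):
            sub = estimates[(estimates["method"] == method)]
            piv = {}
            for occ in ("translucent", "opaque"):
                cond = f"{vision}_{occ}"
                s = sub[sub["condition"] == cond].set_index("participant")
                piv[occ] = s["logmar"].where(s["status"] == "ok")
            participants = sorted(set(piv["translucent"].index) | set(piv["opaque"].index))
            values = np.array(
                [
                    float(piv["translucent"].get(p, np.nan))
                    - float(piv["opaque"].get(p, np.nan))
                    for p in participants
                ]
            )
            diffs = PairedDifferences(values=values, labels=list(participants))
            for statistic in ("median", "mean"):
                row = {
                    "method": method,
                    "vision": vision,
                    "contrast": "translucent_minus_opaque",
                }
                if diffs.n_complete < 2:
                    row.update(
                        {
                            "statistic": statistic,
                            "estimate": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "ci_level": config.ci_level,
                            "p_value": np.nan,
                            "p_bonferroni": np.nan,
                            "bonferroni_factor": config.bonferroni_factor,
                            "n_pairs": diffs.n_complete,
                            "n_missing": diffs.n_missing,
                            "note": "fewer than 2 complete pairs",
                        }
                    )
                else:
                    row.update(
                        compare_conditions(
                            diffs,
                            statistic=statistic,
                            n_permutations=config.n_permutations,
                            n_boot=config.n_boot,
                            level=config.ci_level,
                            bonferroni_factor=config.bonferroni_factor,
                            seed=seed,
                        )
                    )
                    row["note"] = ""
                rows.append(row)
    return pd.DataFrame(rows)


def _package_version() -> str:
    from . import __version__

    return __version__
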