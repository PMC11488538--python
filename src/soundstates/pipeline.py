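"""End-to-end reproducible run: simulate -> metrics -> match -> decode -> statespace."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decoding, matching, responses, simulate, statespace
from .errors import InvalidParameterError
from .protocol import build_session_schedule, build_stimulus_set

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    n_units: int = 40
    n_recordings: int = 2
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(simulate.DEFAULT_CLASS_PROBS)
    )
    silenced_frac: float = simulate.DEFAULT_SILENCED_FRAC
    n_reps: int = 12
    n_splits: int = 25
    mode: str = "time_course"
    jitter_sd: float = 0.05
    match_percentile: float = 95.0
    match_margin: float = 0.2
    n_pcs: int = 3
    n_folds: int = 10
    out_dir: str | None = None

    def validate(self) -> None:
        if self.n_units <= 0 or self.n_reps <= 0 or self.n_splits <= 0:
            raise InvalidParameterError("counts must be positive")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"class_probs must sum to 1, got {total}")
        if not 0.0 <= self.silenced_frac <= 1.0:
            raise InvalidParameterError("silenced_frac must be in [0, 1]")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0]) for c in ss.spawn(n)]


def _bf_sound_index(tw, ta) -> int:
    """Index on the tone grid maximizing the stronger of the two states'
    absolute tuning responses (sign-agnostic best frequency)."""
    score = np.maximum(np.abs(tw.response), np.abs(ta.response))
    return int(np.argmax(score))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return a JSON-serializable report."""
    config.validate()
    seeds = _child_seeds(config.seed, 8)
    report: dict = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": dataclasses.asdict(config),
    }

    # protocol
    stimulus_set = build_stimulus_set(seeds[0])
    schedule = build_session_schedule(stimulus_set, n_reps=config.n_reps, seed=seeds[1])
    durations = stimulus_set.durations()
    report["protocol"] = {
        "n_sounds": len(stimulus_set),
        "category_counts": stimulus_set.category_counts,
        "n_blocks": schedule.n_blocks,
        "n_gaps": len(schedule.gaps),
    }

    # population + tensors
    population = simulate.sample_population(
        config.n_units,
        class_probs=config.class_probs,
        silenced_frac=config.silenced_frac,
        n_recordings=config.n_recordings,
        seed=seeds[2],
    )
    tensors = {
        state: simulate.simulate_response_tensor(
            population, stimulus_set, state, n_trials=config.n_reps, seed=seeds[3] + i
        )
        for i, state in enumerate(simulate.STATES)
    }

    # response metrics: best-frequency recovery and remodel-class recovery
    bf_hits = 0
    bf_total = 0
    class_counts: dict[str, int] = {}
    tone70 = sorted(
        (
            s
            for s in stimulus_set.by_category("pure_tone")
            if float(s.level_db) == 70.0
        ),
        key=lambda s: s.frequency_params["frequencies_khz"][0],
    )
    for u, unit in enumerate(population):
        tw = responses.tuning_curve(tensors["wake"], stimulus_set, u, level_db=70.0)
        ta = responses.tuning_curve(tensors["anesthesia"], stimulus_set, u, level_db=70.0)
        for state, tc in (("wake", tw), ("anesthesia", ta)):
            p = unit.params(state)
            if p.gain >= 10.0:
                bf_total += 1
                if np.isclose(responses.best_frequency(tc), p.best_freq_khz):
                    bf_hits += 1
        bf_sound = tone70[_bf_sound_index(tw, ta)]
        rw, blw = responses.trial_responses_at_sound(
            tensors["wake"], u, bf_sound.sound_id, bf_sound.duration_s
        )
        ra, bla = responses.trial_responses_at_sound(
            tensors["anesthesia"], u, bf_sound.sound_id, bf_sound.duration_s
        )
        label = responses.classify_response_change(rw, ra, blw, bla).value
        class_counts[label] = class_counts.get(label, 0) + 1
    report["metrics"] = {
        "bf_recovery": (bf_hits / bf_total) if bf_total else None,
        "response_change_counts": class_counts,
        "true_class_counts": {
            c: sum(1 for n in population if n.remodel_class == c)
            for c in simulate.REMODEL_CLASSES
        },
    }

    # matching
    wake_t, anes_t = simulate.generate_templates(
        population, jitter_sd=config.jitter_sd, seed=seeds[4]
    )
    match_report: dict = {"n_wake_templates": len(wake_t), "n_anes_templates": len(anes_t)}
    try:
        corr, mask = matching.template_correlation_matrix(wake_t, anes_t)
        thr, null = matching.chance_threshold(corr, mask, config.match_percentile)
        result = matching.match_units(
            corr,
            mask,
            thr,
            config.match_margin,
            [t.unit_id for t in wake_t],
            [t.unit_id for t in anes_t],
        )
        correct = sum(1 for p in result.pairs if p.wake_unit == p.anes_unit)
        truth_pairs = sum(1 for t in anes_t)  # every non-silenced unit has a true pair
        match_report.update(
            threshold=thr,
            n_pairs=len(result.pairs),
            precision=(correct / len(result.pairs)) if result.pairs else None,
            recall=(correct / truth_pairs) if truth_pairs else None,
        )
    except Exception as exc:  # single recording: no chance null
        match_report["error"] = str(exc)
    report["matching"] = match_report

    # decoding
    dec: dict = {}
    for state in simulate.STATES:
        res = decoding.nn_classify(
            tensors[state],
            tensors[state],
            mode=config.mode,
            n_splits=config.n_splits,
            seed=seeds[5],
            durations=durations,
        )
        dec[f"same_state_{state}"] = {
            "mean_accuracy": res.mean_accuracy,
            "sem": res.sem_accuracy,
        }
    cross = decoding.cross_state_design(
        tensors["wake"],
        tensors["anesthesia"],
        mode=config.mode,
        n_splits=config.n_splits,
        seed=seeds[6],
        durations=durations,
    )
    dec["cross_state"] = {
        "wake_to_anes": cross.wake_to_anes.mean_accuracy,
        "anes_to_wake": cross.anes_to_wake.mean_accuracy,
        "mean_accuracy": cross.mean_accuracy,
    }
    dec["chance_level"] = 1.0 / len(stimulus_set)
    report["decoding"] = dec

    # state space
    x, labels, _ = statespace.sound_state_vectors(
        tensors["wake"], tensors["anesthesia"], durations=durations
    )
    pca = statespace.pca_project(x, k=config.n_pcs)
    svm = statespace.svm_state_classification(
        pca.projections, labels, n_folds=config.n_folds, seed=seeds[7]
    )
    rot = statespace.rotate_to_boundary(pca.projections[:, :2], svm.weights[:2])
    report["statespace"] = {
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
        "svm_cv_accuracy": svm.cv_accuracy,
        "pearson_r_normal": rot.pearson_r_normal,
        "pearson_r_collinear": rot.pearson_r_collinear,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
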