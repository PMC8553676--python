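"""ML acuity regression from tuning-curve features.

A small feed-forward network (one hidden layer by default) maps a
scale-free tuning-curve feature vector to logMAR acuity. It is trained on
corpora of tuning curves with known acuity — here synthetic corpora from
:mod:`vepacuity.synthetic` — and carries an explicit range-of-validity
guard: predictions falling outside the logMAR range seen during training
(plus a small margin) are refused rather than extrapolated, because a
regressor trained on one acuity range says nothing about curves far
outside it.

Features per check size: normalized noise-corrected amplitude,
significance flag, log10 spatial frequency; plus one global entry, a 0/1
sentinel that is 0 only for an all-zero curve. Amplitudes are normalized
by the curve maximum (and reduced to single precision, as in the
heuristic fit), so the feature vector — and hence every prediction — is
exactly invariant under a global amplitude scale factor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .heuristic import TuningCurve

#: logMAR margin beyond the training range within which predictions are
#: still accepted.
DEFAULT_RANGE_MARGIN: float = 0.1

N_CHECK_SIZES = 6
FEATURE_LENGTH = N_CHECK_SIZES * 3 + 1


@dataclass(frozen=True)
class CurveFeatures:
    """Fixed-length, scale-free feature vector of one tuning curve."""

    vector: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.vector) != FEATURE_LENGTH:
            raise ValueError(
                f"feature vector must have length {FEATURE_LENGTH}, got {len(self.vector)}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)


#: Feature-vector indices holding discrete values (significance flags and
#: the zero-scale sentinel); used for the input-envelope validity guard.
_DISCRETE_DIMS: tuple[int, ...] = tuple(i * 3 + 1 for i in range(N_CHECK_SIZES)) + (
    FEATURE_LENGTH - 1,
)


@dataclass
class TrainedEstimator:
    """A trained acuity regressor plus its validity metadata.

    ``discrete_envelope`` records, per discrete feature dimension, the set
    of values seen during training; a curve whose significance fingerprint
    was never seen in training is outside the range of validity.
    """

    model: MLPRegressor
    training_range: tuple[float, float]
    n_curves: int
    seed: int
    corpus_hash: str
    margin: float = DEFAULT_RANGE_MARGIN
    discrete_envelope: tuple[frozenset, ...] = ()


@dataclass(frozen=True)
class MLPrediction:
    """Typed prediction outcome: a logMAR value or an explicit refusal."""

    status: str  # "ok" | "refused"
    logmar: float | None = None
    reason: str = ""
    training_range: tuple[float, float] | None = None


def featurize(curve: TuningCurve) -> CurveFeatures:
    """Deterministic, scale-free features of a tuning curve.

    Requires the curve to have exactly six points (the standard stimulus
    set). The all-zero curve maps to zero normalized amplitudes with a
    zero scale sentinel.
    """
    if len(curve.points) != N_CHECK_SIZES:
        raise ValueError(
            f"featurize expects {N_CHECK_SIZES} tuning-curve points, got {len(curve.points)}"
        )
    amps = curve.amplitudes()
    scale = amps.max()
    if scale > 0:
        norm = (amps / scale).astype(np.float32).astype(float)
        sentinel = 1.0
    else:
        norm = np.zeros_like(amps)
        sentinel = 0.0
    sig = [1.0 if curve.is_significant(i) else 0.0 for i in range(len(curve.points))]
    vec = []
    for i in range(N_CHECK_SIZES):
        vec.extend((float(norm[i]), sig[i], float(curve.points[i].log_sf)))
    vec.append(sentinel)
    return CurveFeatures(vector=tuple(vec))


def _corpus_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def train(
    corpus: list[tuple[CurveFeatures, float]],
    seed: int = 0,
    *,
    hidden_layer_sizes: tuple[int, ...] = (32,),
    margin: float = DEFAULT_RANGE_MARGIN,
    max_iter: int = 5000,
) -> TrainedEstimator:
    """Train the acuity regressor on (features, behavioural logMAR) pairs.

    Requires at least 100 pairs with finite, non-degenerate targets.
    Training is reproducible from ``seed`` (deterministic LBFGS fit).
    """
    if len(corpus) < 100:
        raise ValueError(f"need >= 100 training pairs, got {len(corpus)}")
    X = np.array([f.as_array() for f, _ in corpus])
    y = np.array([t for _, t in corpus], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("training targets must be finite")
    if np.ptp(y) == 0:
        raise ValueError("degenerate corpus: all targets identical")
    model = MLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="tanh",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
    )
    model.fit(X, y)
    envelope = tuple(frozenset(float(v) for v in np.unique(X[:, d])) for d in _DISCRETE_DIMS)
    return TrainedEstimator(
        model=model,
        training_range=(float(y.min()), float(y.max())),
        n_curves=len(corpus),
        seed=int(seed),
        corpus_hash=_corpus_hash(X, y),
        margin=margin,
        discrete_envelope=envelope,
    )


def predict(estimator: TrainedEstimator, curve: TuningCurve) -> MLPrediction:
    """Predict logMAR acuity, or refuse outside the range of validity.

    Two guards apply. First, a curve whose significance fingerprint
    (which check sizes responded, or an all-zero curve) was never seen in
    training is refused as outside the training distribution. Second, a
    predicted value outside ``training_range`` widened by ``margin`` on
    each side is refused. Both refusals name the valid range, mirroring
    the behaviour of estimators whose training data did not include such
    acuity levels.
    """
    features = featurize(curve).as_array()
    lo, hi = estimator.training_range
    for dim, seen in zip(_DISCRETE_DIMS, estimator.discrete_envelope):
        if float(features[dim]) not in seen:
            return MLPrediction(
                status="refused",
                reason=(
                    "tuning-curve significance pattern not represented in the "
                    f"training corpus (logMAR range [{lo:.3f}, {hi:.3f}]); the "
                    "estimator was not trained on acuity levels in that range"
                ),
                training_range=estimator.training_range,
            )
    value = float(estimator.model.predict(features[None, :])[0])
    if value < lo - estimator.margin or value > hi + estimator.margin:
        return MLPrediction(
            status="refused",
            reason=(
                f"prediction {value:.3f} logMAR lies outside the training range "
                f"[{lo:.3f}, {hi:.3f}] (margin {estimator.margin:g}); the estimator "
                "was not trained on acuity levels in that range"
            ),
            training_range=estimator.training_range,
        )
    return MLPrediction(status="ok", logmar=value, training_range=estimator.training_range)


def save_estimator(estimator: TrainedEstimator, path: str | Path) -> Path:
    """Serialize a trained estimator (weights + metadata) as JSON."""
    path = Path(path)
    m = estimator.model
    payload = {
        "format": "vepacuity-mlp-v1",
        "hidden_layer_sizes": [int(h) for h in np.atleast_1d(m.hidden_layer_sizes)],
        "activation": m.activation,
        "coefs": [c.tolist() for c in m.coefs_],
        "intercepts": [b.tolist() for b in m.intercepts_],
        "training_range": list(estimator.training_range),
        "n_curves": estimator.n_curves,
        "seed": estimator.seed,
        "corpus_hash": estimator.corpus_hash,
        "margin": estimator.margin,
        "discrete_envelope": [sorted(s) for s in estimator.discrete_envelope],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path


def load_estimator(path: str | Path) -> TrainedEstimator:
    """Load an estimator serialized by :func:`save_estimator`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "vepacuity-mlp-v1":
        raise ValueError(f"unrecognized estimator file format in {path}")
    model = MLPRegressor(
        hidden_layer_sizes=tuple(payload["hidden_layer_sizes"]),
        activation=payload["activation"],
        solver="lbfgs",
    )
    coefs = [np.array(c) for c in payload["coefs"]]
    intercepts = [np.array(b) for b in payload["intercepts"]]
    model.coefs_ = coefs
    model.intercepts_ = intercepts
    model.n_layers_ = len(coefs) + 1
    model.n_outputs_ = 1
    model.out_activation_ = "identity"
    model.n_features_in_ = coefs[0].shape[0]
    return TrainedEstimator(
        model=model,
        training_range=tuple(payload["training_range"]),
        n_curves=payload["n_curves"],
        seed=payload["seed"],
        corpus_hash=payload["corpus_hash"],
        margin=payload["margin"],
        discrete_envelope=tuple(frozenset(s) for s in payload.get("discrete_envelope", [])),
    )


def make_training_corpus(
    n_curves: int,
    seed: int = 0,
    *,
    logmar_range: tuple[float, float] = (-0.2, 0.4),
    noise_sd: float = 20.0,
    blink_rate: float = 0.0,
    stimulus=None,
    conversion_factor=None,
    auto_spurious: bool = True,
) -> list[tuple[TuningCurve, CurveFeatures, float]]:
    """Simulate a labelled corpus of tuning curves for training/evaluation.

    Each curve comes from a fresh simulated participant whose ground-truth
    logMAR is drawn uniformly from ``logmar_range``; the label is that
    ground truth (standing in for behavioural acuity). Returns
    ``(curve, features, logmar)`` triples so callers can also run the
    heuristic on the same curves.
    """
    from .conversion import DEFAULT_CONVERSION_FACTOR
    from .heuristic import build_curve, flag_spurious
    from .spectral import analyze_recording
    from .synthetic import ParticipantModel, StimulusSet, simulate_recording

    stimulus = stimulus or StimulusSet()
    factor = conversion_factor if conversion_factor is not None else DEFAULT_CONVERSION_FACTOR
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 7]))
    out = []
    for i in range(n_curves):
        logmar = float(rng.uniform(*logmar_range))
        participant = ParticipantModel(
            true_logmar_normal=logmar,
            peak_amplitude=float(rng.uniform(6.0, 14.0)),
            noise_sd=noise_sd,
            blink_rate=blink_rate,
            seed=int(rng.integers(0, 2**31)),
            participant_id=f"C{i:04d}",
        )
        responses = [
            analyze_recording(
                simulate_recording(
                    participant, stimulus, c, logmar, conversion_factor=factor
                )
            )
            for c in stimulus.check_sizes
        ]
        curve = build_curve(responses)
        if auto_spurious:
            curve = flag_spurious(curve, "auto")
        out.append((curve, featurize(curve), logmar))
    return out
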