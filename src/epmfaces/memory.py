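"""Episodic Prototypes Model (EPM) core: traces, prototypes, echoes.

The EPM is a hybrid of prototype- and exemplar-based face memory.  Every
experienced face exemplar is stored as a trace, but traces are grouped online
into *episodic prototypes* — temporally contiguous clouds of similar
appearances, each summarised by the running mean (centroid) of its members.

Assimilation of a new exemplar follows a leader-style rule on the *maximum
delta*: the largest Euclidean distance from the incoming exemplar to a
prototype's centroid and all of its member traces.  If even the best
(smallest) maximum delta exceeds a pre-fixed threshold delta, the exemplar is
too different from everything known and seeds a new prototype in a single
step (the rapid-update property); otherwise it is folded into the closest
prototype and the centroid is updated incrementally, so each new member's
influence shrinks as 1/n.

Recognition uses a MINERVA-style *echo*: the probe's cosine similarity S_i to
every trace is sharpened into an activation A_i = S_i**3 (sign-preserving, so
dissimilar traces contribute little) and combined with an exponential recency
weight w_i = 2**(-(now - t_i)/half_life).  The echo intensity is
sum(w_i * A_i) and its content sum(w_i * A_i * f_i).  Prototypicality pools
the echo over all traces; verification takes the best per-prototype echo and
maps its strength to a simulated reaction time through a negative-log linking
function.

Two boundary settings recover the classical models: a threshold delta larger
than the diameter of experience yields one exhaustive prototype (pure
averaging), a zero threshold yields one prototype per distinct exemplar
(pure exemplar memory).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExemplarTrace",
    "EpisodicPrototype",
    "MemoryStore",
    "EchoResult",
    "VerificationResult",
    "trace_similarity",
    "echo",
    "max_delta",
    "assimilate",
    "prototypicality",
    "verify",
]

RT_FLOOR_MS = 200.0        # below this the response is not a valid decision
STRENGTH_FLOOR = 1e-6      # keeps the log-linking finite for null echoes


@dataclass(frozen=True)
class ExemplarTrace:
    """One stored memory trace of an experienced face exemplar."""

    feature_vector: np.ndarray
    encoding_time: float
    exemplar_id: str = ""

    def __post_init__(self):
        vec = np.asarray(self.feature_vector, dtype=float)
        if not np.all(np.isfinite(vec)) or not math.isfinite(self.encoding_time):
            raise ValueError("trace vector and encoding time must be finite")
        object.__setattr__(self, "feature_vector", vec)


@dataclass
class EpisodicPrototype:
    """A temporally contiguous cloud of traces summarised by its centroid."""

    centroid: np.ndarray
    members: list[ExemplarTrace]
    created_at: float

    def __post_init__(self):
        if not self.members:
            raise ValueError("prototype must have at least one member")
        self.centroid = np.asarray(self.centroid, dtype=float)

    @property
    def span(self) -> tuple[float, float]:
        times = [m.encoding_time for m in self.members]
        return (min(times), max(times))

    def add(self, trace: ExemplarTrace, update_centroid: bool = True) -> None:
        """Fold a trace in, updating the centroid as an incremental mean."""
        n = len(self.members)
        if update_centroid:
            self.centroid = self.centroid + (trace.feature_vector - self.centroid) / (n + 1)
        self.members.append(trace)


@dataclass
class MemoryStore:
    """All prototypes of one observer plus the model parameters.

    Parameters
    ----------
    threshold_delta
        Pre-fixed cutoff on the maximum delta above which a new prototype is
        spawned (feature-space distance units).
    recency_half_life
        Half-life of the exponential recency weight, in the same time units
        as encoding times; ``inf`` disables recency weighting.
    update_centroid
        With ``False`` the store runs as a pure leader clusterer: each
        prototype's centroid stays its founding exemplar.  Both variants are
        order-dependent; neither guarantees a monotone prototype count in
        the threshold (absorbing an exemplar early can reshape what later
        exemplars are compared against).
    """

    threshold_delta: float
    recency_half_life: float = math.inf
    prototypes: list[EpisodicPrototype] = field(default_factory=list)
    now: float = 0.0
    update_centroid: bool = True

    def __post_init__(self):
        if self.threshold_delta < 0:
            raise ValueError("threshold_delta must be >= 0")
        if self.recency_half_life <= 0:
            raise ValueError("recency_half_life must be positive (may be inf)")

    @property
    def traces(self) -> list[ExemplarTrace]:
        return [t for p in self.prototypes for t in p.members]

    def recency_weight(self, encoding_time: float) -> float:
        if math.isinf(self.recency_half_life):
            return 1.0
        return 2.0 ** (-(self.now - encoding_time) / self.recency_half_life)

    def memberships(self) -> dict[str, int]:
        """exemplar_id -> prototype index, in creation order."""
        return {t.exemplar_id: i for i, p in enumerate(self.prototypes) for t in p.members}

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "threshold_delta": self.threshold_delta,
            "recency_half_life": self.recency_half_life,
            "now": self.now,
            "update_centroid": self.update_centroid,
            "prototypes": [
                {
                    "centroid": p.centroid.tolist(),
                    "created_at": p.created_at,
                    "members": [
                        {
                            "feature_vector": t.feature_vector.tolist(),
                            "encoding_time": t.encoding_time,
                            "exemplar_id": t.exemplar_id,
                        }
                        for t in p.members
                    ],
                }
                for p in self.prototypes
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MemoryStore":
        doc = json.loads(text)
        store = cls(
            threshold_delta=doc["threshold_delta"],
            recency_half_life=doc["recency_half_life"],
            now=doc["now"],
            update_centroid=doc.get("update_centroid", True),
        )
        for pd_ in doc["prototypes"]:
            members = [
                ExemplarTrace(np.array(m["feature_vector"]), m["encoding_time"], m["exemplar_id"])
                for m in pd_["members"]
            ]
            store.prototypes.append(
                EpisodicPrototype(np.array(pd_["centroid"]), members, pd_["created_at"])
            )
        return store


@dataclass
class EchoResult:
    """Echo of a probe against a set of traces.

    intensity = sum(w_i * A_i) and content = sum(w_i * A_i * f_i), where the
    per-trace tuples (similarity, activation, weight) are kept for audit.
    """

    intensity: float
    content: np.ndarray
    per_trace: list[tuple[float, float, float]]


@dataclass
class VerificationResult:
    match: bool
    strength: float
    latency_ms: float
    best_prototype: int = -1


def trace_similarity(probe_vector: np.ndarray, trace: ExemplarTrace | np.ndarray) -> float:
    """Cosine similarity between probe and stored trace, in [-1, 1]."""
    probe = np.asarray(probe_vector, dtype=float)
    vec = trace.feature_vector if isinstance(trace, ExemplarTrace) else np.asarray(trace, float)
    if probe.shape != vec.shape:
        raise ValueError("probe and trace dimensions differ")
    pn = np.linalg.norm(probe)
    if pn == 0:
        raise ValueError("probe vector must be nonzero")
    tn = np.linalg.norm(vec)
    if tn == 0:
        return 0.0
    return float(np.clip(probe @ vec / (pn * tn), -1.0, 1.0))


def _echo_over(probe: np.ndarray, traces: list[ExemplarTrace], store: MemoryStore) -> EchoResult:
    per_trace = []
    intensity = 0.0
    content = np.zeros_like(np.asarray(probe, dtype=float))
    for t in traces:
        s = trace_similarity(probe, t)
        a = s ** 3
        w = store.recency_weight(t.encoding_time)
        per_trace.append((s, a, w))
        intensity += w * a
        content = content + w * a * t.feature_vector
    return EchoResult(float(intensity), content, per_trace)


def echo(probe_vector: np.ndarray, store: MemoryStore) -> EchoResult:
    """Pooled echo of a probe against every trace in the store."""
    if not store.prototypes:
        raise ValueError("echo of an empty store is undefined")
    return _echo_over(probe_vector, store.traces, store)


def max_delta(exemplar: np.ndarray, prototype: EpisodicPrototype) -> float:
    """Largest Euclidean distance from the exemplar to centroid and members."""
    vec = np.asarray(exemplar, dtype=float)
    if vec.shape != prototype.centroid.shape:
        raise ValueError("dimension mismatch")
    d = np.linalg.norm(vec - prototype.centroid)
    for m in prototype.members:
        d = max(d, np.linalg.norm(vec - m.feature_vector))
    return float(d)


def assimilate(store: MemoryStore, exemplar: ExemplarTrace | np.ndarray,
               time: float | None = None, exemplar_id: str = "") -> MemoryStore:
    """Fold one new exemplar into the store (in place) and return it.

    The stream must be chronological: ``time`` may not precede ``store.now``.
    Ties on the minimum maximum-delta go to the most recently created
    prototype.
    """
    if isinstance(exemplar, ExemplarTrace):
        trace = exemplar if time is None else ExemplarTrace(exemplar.feature_vector, time, exemplar.exemplar_id)
    else:
        if time is None:
            raise ValueError("time is required for a bare feature vector")
        trace = ExemplarTrace(np.asarray(exemplar, dtype=float), time, exemplar_id)

    if store.prototypes and trace.encoding_time < store.now:
        raise ValueError(
            f"non-chronological stream: time {trace.encoding_time} < store.now {store.now}"
        )

    best_idx, best_delta = -1, math.inf
    for i, proto in enumerate(store.prototypes):
        d = max_delta(trace.feature_vector, proto)
        if d < best_delta or (d == best_delta and best_idx >= 0
                              and proto.created_at >= store.prototypes[best_idx].created_at):
            best_idx, best_delta = i, d

    if best_idx < 0 or best_delta > store.threshold_delta:
        store.prototypes.append(
            EpisodicPrototype(trace.feature_vector.copy(), [trace], trace.encoding_time)
        )
    else:
        store.prototypes[best_idx].add(trace, update_centroid=store.update_centroid)
    store.now = trace.encoding_time
    return store


def prototypicality(store: MemoryStore, probe_vector: np.ndarray) -> float:
    """Recency-weighted pooled echo intensity — larger is more prototypical."""
    return echo(probe_vector, store).intensity


def verify(store: MemoryStore, probe_vector: np.ndarray, decision_threshold: float,
           rt_params: tuple[float, float] = (800.0, 100.0)) -> VerificationResult:
    """Match the probe to the prototype with the strongest echo.

    The echo is computed per prototype (over that prototype's members only)
    and the strongest one is the decision variable.  Latency follows
    ``base_ms - slope_ms * ln(max(strength, 1e-6))``, clamped below at the
    200 ms validity floor.
    """
    if not store.prototypes:
        raise ValueError("cannot verify against an empty store")
    base_ms, slope_ms = rt_params
    if slope_ms <= 0:
        raise ValueError("rt slope must be positive")
    strengths = [_echo_over(probe_vector, p.members, store).intensity for p in store.prototypes]
    best = int(np.argmax(strengths))
    strength = float(strengths[best])
    latency = base_ms - slope_ms * math.log(max(strength, STRENGTH_FLOOR))
    return VerificationResult(
        match=strength >= decision_threshold,
        strength=strength,
        latency_ms=float(max(latency, RT_FLOOR_MS)),
        best_prototype=best,
    )
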