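"""Episodic, exhaustive, and leave-one-out prototype construction.

In the photographic studies a prototype is an image morph over a set of face
exemplars; here the morph is represented by its feature-space analogue, the
centroid of the member feature vectors.  That abstraction — averaging feature
vectors in place of landmark-based image morphing — is the core simplification
of this package.

Leave-one-out versions recompute the centroid with one member excluded, which
yields as many non-identical probe stimuli per prototype as it has members
while preserving the prototype's central tendency (the mean of all LOO
centroids equals the full centroid exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LifespanTrajectory

__all__ = [
    "PrototypeVersion",
    "episodic_prototypes",
    "exhaustive_prototype",
    "loo_versions",
    "decade_tag",
]


@dataclass(frozen=True)
class PrototypeVersion:
    """A centroid over a member set, optionally with one member left out."""

    centroid: np.ndarray
    member_ids: tuple
    episode_tag: str
    excluded_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if self.excluded_id is not None and self.excluded_id in self.member_ids:
            raise ValueError("excluded member listed among included members")


def decade_tag(ages, birth_year: int = 1955) -> str:
    """Episode tag from the members' capture-age span, as decade labels."""
    lo, hi = min(ages), max(ages)
    d0 = (birth_year + int(lo)) // 10 * 10
    d1 = (birth_year + int(hi)) // 10 * 10
    return f"{d0}s" if d0 == d1 else f"{d0}s-{d1}s"


def episodic_prototypes(trajectory: LifespanTrajectory, labels,
                        birth_year: int = 1955) -> list[PrototypeVersion]:
    """One prototype per cluster of the trajectory's exemplars.

    ``labels`` assigns a cluster index to every exemplar (in age order).
    Prototypes are returned ordered by their clusters' mean capture age, so
    index 0 is the earliest episode and the last entry the most recent one.
    """
    labels = np.asarray(labels)
    feats = trajectory.features
    if len(labels) != len(feats):
        raise ValueError("labels must cover all exemplars")
    ages = trajectory.ages
    ids = np.array([e.exemplar_id for e in trajectory.exemplars])
    out = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            raise ValueError("empty cluster")
        out.append(
            PrototypeVersion(
                centroid=feats[idx].mean(axis=0),
                member_ids=tuple(ids[idx]),
                episode_tag=decade_tag(ages[idx], birth_year),
            )
        )
    out.sort(key=lambda p: float(np.mean([ages[np.flatnonzero(ids == m)[0]] for m in p.member_ids])))
    return out


def exhaustive_prototype(trajectory: LifespanTrajectory) -> PrototypeVersion:
    """Centroid over every exemplar of the identity's whole observed lifespan."""
    feats = trajectory.features
    if len(feats) < 1:
        raise ValueError("trajectory has no exemplars")
    ids = tuple(e.exemplar_id for e in trajectory.exemplars)
    return PrototypeVersion(feats.mean(axis=0), ids, "exhaustive")


def loo_versions(members: list[tuple[str, np.ndarray]] | PrototypeVersion,
                 features_by_id: dict | None = None,
                 episode_tag: str | None = None) -> list[PrototypeVersion]:
    """Leave-one-out versions: one per member, each excluding that member.

    Accepts either a list of ``(member_id, feature_vector)`` pairs or a
    ``PrototypeVersion`` plus a ``features_by_id`` lookup.
    """
    if isinstance(members, PrototypeVersion):
        if features_by_id is None:
            raise ValueError("features_by_id required with a PrototypeVersion input")
        tag = episode_tag or members.episode_tag
        pairs = [(m, np.asarray(features_by_id[m], dtype=float)) for m in members.member_ids]
    else:
        tag = episode_tag or "loo"
        pairs = [(m, np.asarray(v, dtype=float)) for m, v in members]
    if len(pairs) < 2:
        raise ValueError("leave-one-out needs at least 2 members")
    feats = np.vstack([v for _, v in pairs])
    total = feats.sum(axis=0)
    n = len(pairs)
    return [
        PrototypeVersion(
            centroid=(total - feats[i]) / (n - 1),
            member_ids=tuple(m for j, (m, _) in enumerate(pairs) if j != i),
            episode_tag=tag,
            excluded_id=pairs[i][0],
        )
        for i in range(n)
    ]
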