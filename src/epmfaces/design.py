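"""Experiment-design enumeration and statistical helper computations.

Covers the closed-form trial arithmetic of the rating and verification
designs (pairwise displays, repeated-evaluation blocks, counterbalanced
verification sets), the reaction-time outlier rule, and the effect-size /
aggregation identities used to summarise results: pooled-SD Cohen's d,
partial eta-squared from F and its degrees of freedom, and Fisher-Z-averaged
per-participant correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialSet",
    "EffectSize",
    "RegressionSummary",
    "pairwise_displays",
    "ret_trials",
    "verification_trial_set",
    "rt_filter",
    "cohen_d",
    "partial_eta_sq",
    "fisherz_r2",
]

RT_FLOOR_MS = 200.0
RT_SD_CRITERION = 2.5


@dataclass
class TrialSet:
    """An ordered list of trial records with per-condition counts."""

    trials: list[dict]
    counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trials)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EffectSize:
    kind: str
    value: float
    inputs: dict


@dataclass(frozen=True)
class RegressionSummary:
    """Per-participant correlations aggregated through Fisher's Z."""

    r_values: tuple
    r_squared: float
    slope_sign: int


def pairwise_displays(n_items: int) -> TrialSet:
    """All C(n, 2) unordered pairs of items, each shown once."""
    if n_items < 2:
        raise ValueError("need at least 2 items to form pairs")
    trials = [
        {"left": i, "right": j, "condition": "pair"}
        for i, j in itertools.combinations(range(n_items), 2)
    ]
    return TrialSet(trials, {"pair": len(trials)})


def ret_trials(n_items: int, n_vars: int, n_reps: int,
               block_random_seed: int = 0) -> TrialSet:
    """Repeated-evaluation trials: items × variables, blockwise shuffled.

    Each repetition is a block; the item × variable pairs are shuffled
    independently within each block.
    """
    if min(n_items, n_vars, n_reps) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(block_random_seed)
    trials = []
    base = list(itertools.product(range(n_items), range(n_vars)))
    for rep in range(n_reps):
        order = rng.permutation(len(base))
        for idx in order:
            item, var = base[idx]
            trials.append({"block": rep, "item": item, "variable": var, "condition": "ret"})
    return TrialSet(trials, {"ret": len(trials), "per_block": n_items * n_vars, "blocks": n_reps})


def _infer_sex(model_id: str) -> str:
    low = str(model_id).lower()
    if low.startswith("f"):
        return "female"
    if low.startswith("m"):
        return "male"
    raise ValueError(f"cannot infer sex from model id {model_id!r}; pass sex_map")


def verification_trial_set(ep_versions_by_model: dict, exhaustive_versions_by_model: dict,
                           name_map: dict, seed: int = 0,
                           sex_map: dict | None = None) -> TrialSet:
    """One verification trial per prototype version, names counterbalanced.

    Every version (episodic and exhaustive, all models pooled) appears once.
    Half of each model's trials pair the face with its own name (match) and
    half with the name of another model of the same sex (mismatch); with an
    odd count the split differs by one.  Trial order is shuffled by seed.
    """
    if not ep_versions_by_model and not exhaustive_versions_by_model:
        raise ValueError("no versions supplied")
    models = sorted(set(ep_versions_by_model) | set(exhaustive_versions_by_model))
    missing = [m for m in models if m not in name_map]
    if missing:
        raise ValueError(f"name_map missing models: {missing}")
    sex_of = {m: (sex_map[m] if sex_map else _infer_sex(m)) for m in models}
    rng = np.random.default_rng(seed)

    trials = []
    odd_toggle = {"female": True, "male": True}
    for model in models:
        versions = [("episodic", v) for v in ep_versions_by_model.get(model, [])]
        versions += [("exhaustive", v) for v in exhaustive_versions_by_model.get(model, [])]
        same_sex_others = [m for m in models if m != model and sex_of[m] == sex_of[model]]
        # counterbalanced match/mismatch assignment; with an odd version
        # count the extra match alternates between the sex's models so the
        # per-sex split also differs by at most one
        n = len(versions)
        n_match = n // 2
        if n % 2:
            sex = sex_of[model]
            toggle = odd_toggle.setdefault(sex, True)
            n_match += 1 if toggle else 0
            odd_toggle[sex] = not toggle
        is_match = np.array([True] * n_match + [False] * (n - n_match))
        rng.shuffle(is_match)
        for (cond, version), match in zip(versions, is_match):
            if match or not same_sex_others:
                name = name_map[model]
            else:
                name = name_map[same_sex_others[int(rng.integers(len(same_sex_others)))]]
            tag = getattr(version, "episode_tag", cond)
            trials.append({
                "model": model,
                "condition": cond,
                "episode_tag": tag,
                "version": getattr(version, "excluded_id", None) or str(version),
                "name": name,
                "is_match": bool(match or not same_sex_others),
            })
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    counts: dict = {}
    for t in trials:
        counts[t["condition"]] = counts.get(t["condition"], 0) + 1
    counts["total"] = len(trials)
    return TrialSet(trials, counts)


def rt_filter(rts_by_participant: dict) -> tuple[dict, dict, float]:
    """Remove reaction-time outliers with the 200 ms / 2.5 SD rule.

    A single pass per participant: the mean and SD are computed once on the
    raw list, then any RT below the global 200 ms floor or above
    mean + 2.5*SD is removed.  Returns (kept, removed, global loss fraction).
    """
    if not rts_by_participant:
        raise ValueError("empty input")
    kept: dict = {}
    removed: dict = {}
    total = lost = 0
    for pid, rts in rts_by_participant.items():
        rts = list(rts)
        if not rts:
            raise ValueError(f"participant {pid!r} has no RTs")
        arr = np.asarray(rts, dtype=float)
        mean = arr.mean()
        sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
        upper = mean + RT_SD_CRITERION * sd
        keep_mask = (arr >= RT_FLOOR_MS) & (arr <= upper)
        kept[pid] = arr[keep_mask].tolist()
        removed[pid] = arr[~keep_mask].tolist()
        total += len(arr)
        lost += int((~keep_mask).sum())
    return kept, removed, lost / total


def cohen_d(m1: float, sd1: float, m2: float, sd2: float) -> EffectSize:
    """Pooled-SD Cohen's d: (m1 - m2) / sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both SDs are zero; d is undefined")
    d = (m1 - m2) / math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    return EffectSize("cohen_d", d, {"m1": m1, "sd1": sd1, "m2": m2, "sd2": sd2})


def partial_eta_sq(F: float, df1: int, df2: int) -> EffectSize:
    """Partial eta-squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    value = F * df1 / (F * df1 + df2)
    return EffectSize("partial_eta_sq", value, {"F": F, "df1": df1, "df2": df2})


def fisherz_r2(per_participant_r) -> RegressionSummary:
    """Aggregate per-participant correlations: r^2 = tanh(mean(atanh(r)))^2."""
    r = np.asarray(list(per_participant_r), dtype=float)
    if r.size == 0:
        raise ValueError("no correlations supplied")
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    mean_z = np.arctanh(r).mean()
    pooled_r = math.tanh(mean_z)
    return RegressionSummary(tuple(r.tolist()), pooled_r ** 2, int(np.sign(pooled_r)))
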