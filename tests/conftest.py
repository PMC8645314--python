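import numpy as np
import pytest

from epmfaces.synthetic import FaceExemplar, LifespanTrajectory


# four well-separated episode centres in a 2-D appearance plane, arranged so
# that the two-step pipeline's k-selection criteria have power (synthetic
# stand-in for a lifespan with three sudden appearance changes)
EPISODE_CENTERS = np.array([[15.3, 19.6], [0.6, 2.1], [3.1, 11.6], [8.6, 1.3]])


def four_episode_trajectory(seed: int = 0, n_per: int = 5, sd: float = 0.8) -> LifespanTrajectory:
    """Constructed 4-episode trajectory: 3 jumps, tight within-episode noise."""
    rng = np.random.default_rng(seed)
    exemplars = []
    age = 0.0
    for center in EPISODE_CENTERS:
        for _ in range(n_per):
            feat = center + rng.normal(0.0, sd, 2)
            exemplars.append(FaceExemplar(f"e{len(exemplars):02d}", "fix", age, feat))
            age += 1.5
    jumps = [
        (n_per * 1.5 * k - 0.5, float(np.linalg.norm(EPISODE_CENTERS[k] - EPISODE_CENTERS[k - 1])))
        for k in (1, 2, 3)
    ]
    return LifespanTrajectory("fix", exemplars, jumps)


@pytest.fixture
def episode_trajectory():
    return four_episode_trajectory(seed=0)
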