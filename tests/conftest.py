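import math

import numpy as np
import pytest

from mousegait.config import RunConfig
from mousegait.simulate import SyntheticGaitConfig, generate_run


def brute_force_clusters(coords: np.ndarray, threshold: float) -> set[frozenset]:
    """Independent O(n^2) single-linkage oracle: build the full pairwise
    adjacency at ``threshold`` and take transitive closures by BFS."""
    n = len(coords)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            if math.hypot(dx, dy) <= threshold:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = set()
    for i in range(n):
        if seen[i]:
            continue
        stack, members = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            members.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.add(frozenset(members))
    return comps


@pytest.fixture(scope="session")
def oracle_cluster():
    return brute_force_clusters


def run_config_for(sim_cfg: SyntheticGaitConfig) -> RunConfig:
    """Pipeline config matched to a synthetic run's geometry: identity
    preprocessing and the analysis band at the synthetic enclosure rows."""
    rc = RunConfig()
    rc.preprocess.enclosure_y_top = sim_cfg.enclosure_y_top
    rc.preprocess.enclosure_y_bottom = sim_cfg.enclosure_y_bottom
    return rc


@pytest.fixture(scope="session")
def clean_cfg() -> SyntheticGaitConfig:
    return SyntheticGaitConfig(rng_seed=11)


@pytest.fixture(scope="session")
def clean_run(clean_cfg):
    return generate_run(clean_cfg)


@pytest.fixture(scope="session")
def clean_run_config(clean_cfg) -> RunConfig:
    return run_config_for(clean_cfg)
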