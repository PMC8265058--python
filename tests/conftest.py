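"""Shared fixtures: all data are generated programmatically at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lvfractal.phantom import generate_cine_stack, profile_for_group
from lvfractal.pipeline import RunConfig, run_subject

warnings.filterwarnings("ignore", category=FutureWarning)

GROUPS = ("lvnc", "hypertrabeculated", "normal")


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Three phantoms per group with ground truth, seeds fixed."""
    out = []
    for group in GROUPS:
        for seed in (11, 12, 13):
            stack, truth = generate_cine_stack(profile_for_group(group, seed=seed))
            out.append((stack, truth, group))
    return out


@pytest.fixture(scope="session")
def analyzed_small_cohort(default_config, small_cohort):
    """Subject results for the small cohort (shared across test modules)."""
    return [
        (run_subject(default_config, stack, truth=truth, group=group), truth, group)
        for stack, truth, group in small_cohort
    ]


@pytest.fixture(scope="session")
def acceptance_cohort(default_config):
    """28 phantoms per group analyzed through the full pipeline.

    Seeds 1..84 assigned group-blockwise; results carry per-slice FDs,
    aggregates and comparator indices.  Session-scoped because several
    cohort-level properties are checked against the same experiment.
    """
    results = []
    seed = 0
    for group in GROUPS:
        for _ in range(28):
            seed += 1
            stack, truth = generate_cine_stack(profile_for_group(group, seed=seed))
            results.append(
                (run_subject(default_config, stack, truth=truth, group=group), group)
            )
    return results


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
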