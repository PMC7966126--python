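import numpy as np
import pytest

import irtlink as il


@pytest.fixture(scope="session")
def scale():
    """The packaged synthetic 33-item, 5-category reference scale."""
    return il.reference_scale()


@pytest.fixture(scope="session")
def linkset(scale):
    """Fitted pn1..pn4 for the reference scale (built once per session)."""
    return il.build_linkset(scale)


@pytest.fixture(scope="session")
def toy_scale():
    """Two 3-category items: small enough for exact joint enumeration."""
    return il.ScaleDefinition(
        items=(
            il.ItemParams("a", 1.2, (-0.5, 0.8), (0, 1, 2)),
            il.ItemParams("b", 0.7, (0.1, 1.4), (0, 1, 2)),
        ),
        name="toy-2x3",
        psi_domain=(-3.0, 3.0),
    )


@pytest.fixture(scope="session")
def binary_item():
    return il.ItemParams("bin", 1.3, (0.4,), (0, 1))


@pytest.fixture(scope="session")
def small_study(scale):
    """A 60-subject no-progression study used by estimation tests."""
    design = il.StudyDesign(n_subjects=60, times=(0.0, 0.5, 1.0, 1.5, 2.0))
    truth = il.TruthSpec(baseline=0.654, slope=0.0, omega_baseline=1.0)
    _, dataset = il.simulate_study(scale, design, truth, seed=2024)
    return dataset


def enumerate_joint(scale_def):
    """Brute-force oracle: all outcome combinations of a small scale.

    Returns (total_scores, joint_prob_fn) where joint_prob_fn(psi) gives
    the probability of each combination under conditional independence.
    """
    import itertools

    combos = list(itertools.product(*[range(it.n_categories) for it in scale_def.items]))
    totals = np.array(
        [sum(it.category_scores[c] for it, c in zip(scale_def.items, combo))
         for combo in combos]
    )

    def probs(psi):
        per_item = [np.asarray(il.category_probs(it, float(psi))) for it in scale_def.items]
        return np.array(
            [np.prod([p[c] for p, c in zip(per_item, combo)]) for combo in combos]
        )

    return totals, probs
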