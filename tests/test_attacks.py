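"""Attack mathematics: budgets, projections, reductions and gradients.

The analytic oracle is a hand-set linear-softmax model whose loss gradient
with respect to the pixels is available in closed form (and cross-checked
by finite differences), so the FGSM direction and the PGD fixed point can
be predicted exactly.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import advdefend.nn as nn
from advdefend import AttackSpec, ImageBatch, fgsm, generate_attack_suite, pgd
from advdefend.attacks import DEFAULT_EPSILONS, attack
from advdefend.errors import CapabilityError, DataError


class LinearSoftmaxModel:
    """logits = X @ W + b on flattened pixels; exact input gradients."""

    def __init__(self, W, b):
        self.W, self.b = np.asarray(W, float), np.asarray(b, float)

    def logits(self, pixels):
        flat = np.asarray(pixels).reshape(len(pixels), -1)
        return flat @ self.W + self.b

    def input_gradient(self, pixels, labels):
        p = nn.softmax(self.logits(pixels))
        n = len(p)
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        flat_grad = (d / n) @ self.W.T
        return flat_grad.reshape(np.asarray(pixels).shape)

    def predict(self, batch):
        p = nn.softmax(self.logits(batch.pixels))
        return p, p.argmax(-1)


@pytest.fixture
def two_pixel_problem():
    # 2 pixels, 3 classes; weights chosen so gradient signs are unambiguous
    W = np.array([[2.0, -1.0, 0.5], [-1.5, 1.0, 0.25]])
    b = np.array([0.1, -0.2, 0.0])
    model = LinearSoftmaxModel(W, b)
    pixels = np.array([[0.4, 0.6]], np.float32).reshape(1, 1, 2, 1)
    batch = ImageBatch(pixels, [0], ["a"])
    return model, batch


class TestFGSM:
    def test_zero_epsilon_is_identity(self, two_pixel_problem):
        model, batch = two_pixel_problem
        adv = fgsm(model, batch, AttackSpec("fgsm", 0.0))
        assert np.array_equal(adv.perturbed.pixels, batch.pixels)

    @pytest.mark.parametrize("eps", [0.001, 0.05, 0.4])
    def test_budget_bound_and_range(self, untrained_tiny_model, tiny_dataset,
                                    eps):
        batch = tiny_dataset.test
        adv = fgsm(untrained_tiny_model, batch, AttackSpec("fgsm", eps))
        delta = np.abs(adv.perturbed.pixels - batch.pixels)
        assert delta.max() <= eps + 1e-6
        assert adv.perturbed.pixels.min() >= 0
        assert adv.perturbed.pixels.max() <= 1
        assert np.all(adv.linf <= eps + 1e-6)

    def test_direction_matches_finite_difference_oracle(self, two_pixel_problem):
        model, batch = two_pixel_problem
        y = batch.labels
        # finite-difference gradient of the cross-entropy at each pixel
        def loss(px):
            l, _ = nn.softmax_cross_entropy(model.logits(px), y)
            return l
        g_fd = np.zeros(2)
        for j in range(2):
            for s, sgn in ((1e-6, 1), (-1e-6, -1)):
                px = batch.pixels.astype(np.float64).reshape(1, 1, 2, 1)
                px[0, 0, j, 0] += s
                g_fd[j] += sgn * loss(px)
        g_fd /= 2e-6
        g = model.input_gradient(batch.pixels, y).ravel()
        assert g == pytest.approx(g_fd, abs=1e-8)
        # unclipped pixels move exactly to x + eps*sign(g)
        eps = 0.05
        adv = fgsm(model, batch, AttackSpec("fgsm", eps))
        expected = batch.pixels.ravel() + eps * np.sign(g)
        assert adv.perturbed.pixels.ravel() == pytest.approx(expected)

    @given(eps=st.floats(0.0, 0.5), data_seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_budget_range_and_labels_for_arbitrary_inputs(self, eps,
                                                          data_seed):
        model = LinearSoftmaxModel([[2.0, -1.0, 0.5], [-1.5, 1.0, 0.25]],
                                   [0.1, -0.2, 0.0])
        rng = np.random.default_rng(data_seed)
        px = rng.random((3, 1, 2, 1), dtype=np.float32)
        batch = ImageBatch(px, rng.integers(0, 3, 3), ["a", "b", "c"])
        adv = fgsm(model, batch, AttackSpec("fgsm", eps))
        assert np.abs(adv.perturbed.pixels - px).max() <= eps + 1e-6
        assert adv.perturbed.pixels.min() >= 0
        assert adv.perturbed.pixels.max() <= 1
        assert np.array_equal(adv.perturbed.labels, batch.labels)

    def test_clean_batch_is_immutable(self, two_pixel_problem):
        model, batch = two_pixel_problem
        before = batch.pixels.copy()
        fgsm(model, batch, AttackSpec("fgsm", 0.3))
        assert np.array_equal(batch.pixels, before)

    def test_labels_pass_through(self, untrained_tiny_model, tiny_dataset):
        adv = fgsm(untrained_tiny_model, tiny_dataset.test,
                   AttackSpec("fgsm", 0.1))
        assert np.array_equal(adv.perturbed.labels, tiny_dataset.test.labels)

    def test_non_differentiable_model_rejected(self, tiny_dataset):
        with pytest.raises(CapabilityError):
            fgsm(object(), tiny_dataset.test, AttackSpec("fgsm", 0.1))


class TestPGD:
    def test_single_big_step_reduces_to_fgsm(self, untrained_tiny_model,
                                             tiny_dataset):
        batch = tiny_dataset.test
        eps = 0.05
        a = fgsm(untrained_tiny_model, batch, AttackSpec("fgsm", eps))
        b = pgd(untrained_tiny_model, batch,
                AttackSpec("pgd", eps, n_iter=1, step_size=eps))
        assert np.allclose(a.perturbed.pixels, b.perturbed.pixels, atol=1e-7)

    def test_iterates_stay_in_ball_and_range(self, untrained_tiny_model,
                                             tiny_dataset):
        batch = tiny_dataset.test
        eps = 0.1
        adv = pgd(untrained_tiny_model, batch,
                  AttackSpec("pgd", eps, n_iter=5, random_start=True, seed=1))
        delta = np.abs(adv.perturbed.pixels - batch.pixels)
        assert delta.max() <= eps + 1e-6
        assert adv.perturbed.pixels.min() >= 0
        assert adv.perturbed.pixels.max() <= 1

    def test_linear_model_reaches_epsilon_corner(self, two_pixel_problem):
        """On a linear model the loss is monotone along sign(g): enough
        small steps drive every (unclipped) pixel to the predicted corner
        of the epsilon ball."""
        model, batch = two_pixel_problem
        g = model.input_gradient(batch.pixels, batch.labels)
        eps = 0.05
        adv = pgd(model, batch,
                  AttackSpec("pgd", eps, n_iter=20, step_size=eps / 8))
        expected = batch.pixels + eps * np.sign(g)
        assert adv.perturbed.pixels == pytest.approx(expected, abs=1e-7)

    def test_schedule_validation(self):
        with pytest.raises(DataError):
            AttackSpec("pgd", 0.1, n_iter=0)
        with pytest.raises(DataError):
            AttackSpec("pgd", 0.1, step_size=-1.0)
        with pytest.raises(DataError):
            AttackSpec("unknown", 0.1)
        with pytest.raises(DataError):
            AttackSpec("fgsm", -0.1)


class TestAttackSuite:
    def test_minimal_counting(self, untrained_tiny_model, tiny_dataset):
        specs = [AttackSpec("fgsm", 0.05)]
        out = generate_attack_suite(untrained_tiny_model, tiny_dataset, specs,
                                    {"train": 1, "test": 1, "validation": 1})
        assert len(out) == 9  # 3 splits x 3 classes
        assert sum(len(b) for b in out.values()) == 9

    def test_selection_is_first_k_by_sorted_id(self, untrained_tiny_model,
                                               tiny_dataset):
        out = generate_attack_suite(
            untrained_tiny_model, tiny_dataset,
            [AttackSpec("fgsm", 0.0)],
            {"train": 2, "test": 2, "validation": 2})
        batch = out[("fgsm", 0.0, "train", "bacterial")]
        expected = sorted(tiny_dataset.train.select_class(0).ids)[:2]
        assert list(batch.ids) == expected

    def test_insufficient_images_error_names_split_and_class(
            self, untrained_tiny_model, tiny_dataset):
        with pytest.raises(DataError, match="train.*bacterial|bacterial.*train"):
            generate_attack_suite(untrained_tiny_model, tiny_dataset,
                                  [AttackSpec("fgsm", 0.1)],
                                  {"train": 999, "test": 1, "validation": 1})

    def test_default_epsilon_grid(self):
        assert DEFAULT_EPSILONS == (0.001, 0.006, 0.05, 0.1, 0.4)


class TestEmpiricalAttackStrength:
    """Monotonicity properties on the trained 32px benchmark model."""

    def test_accuracy_nonincreasing_in_epsilon(self, benchmark_reports):
        """Mean over seeds: accuracy never rises with the budget up to
        eps = 0.1 (small wiggle tolerance); at extreme budgets the signal
        is destroyed, so accuracy may drift back toward - but not above -
        the 3-class chance floor."""
        import pandas as pd
        frames = pd.concat(benchmark_reports.values())
        sub = frames[(frames.defense == "none") & (frames.attack != "none")]
        mean = sub.groupby(["attack", "epsilon"]).accuracy.mean()
        for fam in ("fgsm", "pgd"):
            acc = mean[fam].sort_index()
            upto = acc[acc.index <= 0.1].to_numpy()
            assert np.all(np.diff(upto) <= 2.0), acc
            # chance floor: no recovery above ~1/3 once the attack saturates
            assert (acc[acc.index >= 0.05] <= 100 / 3 + 2.0).all(), acc

    def test_pgd_at_least_as_damaging_as_fgsm_on_average(self,
                                                         benchmark_reports):
        """Mean over seeds: PGD accuracy <= FGSM accuracy + 5pt tolerance
        at every shared epsilon — the iterative attack is the stronger one."""
        import pandas as pd
        frames = pd.concat(benchmark_reports.values())
        sub = frames[(frames.defense == "none") & (frames.attack != "none")]
        mean = sub.groupby(["attack", "epsilon"]).accuracy.mean().unstack(0)
        assert (mean["pgd"] <= mean["fgsm"] + 5.0).all()
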