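"""Feedforward networks that learn to solve the assignment problem.

Two stimuli, each with ``K = 3`` features (one common ``c``, two unique
``u_x``, ``u_y``), are encoded by two noisy receptive-field input
populations: ``R_X`` sees ``(c, u_x)`` and ``R_Y`` sees ``(c, u_y)``
(``C = 1`` overlap, SNR 20 each). A feedforward network maps the
concatenated noisy inputs to an output population that represents the two
*bound* unique-feature pairs ``(u_x, u_y)`` — the common feature is
marginalized out. Producing the correct output requires solving the
assignment problem: deciding which ``u_x`` goes with which ``u_y``.

Variants (mirroring how much structure the training signal imposes):

- ``end_to_end``: trained only on the output target, with or without
  intervening hidden + integration layers;
- ``integration_learning``: the integration layer is additionally trained
  to reproduce a noiseless ``K = 3`` receptive-field representation of both
  stimuli (the bound, pre-marginalization representation); the output is a
  second objective.

Evaluation asks whether the network's output is closer to the correct
output target or to the prototypical assignment error (the two stimuli's
unique features exchanged), binned by the true common-feature distance
``delta``; the theoretical floor is the crossing probability ``F(delta)``
computed from the input codes' common-feature local MSE.

The networks are small dense ReLU MLPs with a linear output head, trained
by Adam on mean squared error; implemented directly on numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import rf_code
from .theory import NoiseSpec, crossing_probability

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "ExperimentCodes",
    "EvalResult",
    "Network",
    "make_codes",
    "generate_trial",
    "generate_trials",
    "build_network",
    "train",
    "evaluate_assignment",
    "run_variant",
    "ramp_input_experiment",
    "DEFAULT_VARIANTS",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture switchboard for the four variants."""

    variant: str = "integration_learning"  # "end_to_end" | "integration_learning"
    has_hidden: bool = True
    has_integration_layer: bool = True
    n_inputs: int = 256
    n_hidden: int = 256
    n_integration: int = 256
    n_output: int = 128

    def __post_init__(self) -> None:
        if self.variant not in ("end_to_end", "integration_learning"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "integration_learning" and not self.has_integration_layer:
            raise ValueError("integration learning requires an integration layer")

    def layer_sizes(self) -> list[int]:
        sizes = [self.n_inputs]
        if self.has_hidden:
            sizes += [self.n_hidden, self.n_hidden]
        if self.has_integration_layer:
            sizes += [self.n_integration]
        sizes += [self.n_output]
        return sizes


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 200
    max_epochs: int = 30
    n_samples: int = 10_000
    early_stop_patience: int = 2
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    integration_loss_weight: float = 1.0
    output_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "max_epochs", "n_samples", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ExperimentCodes:
    """The fixed input/target populations shared across trials."""

    pop_x: rf_code.RFPopulation  # encodes (common, unique_x)
    pop_y: rf_code.RFPopulation  # encodes (common, unique_y)
    pop_integration: rf_code.RFPopulation  # encodes (common, unique_x, unique_y)
    pop_output: rf_code.RFPopulation  # encodes (unique_x, unique_y)
    snr: float


def make_codes(
    n_input_units: int = 128,
    n_integration_units: int = 256,
    n_output_units: int = 128,
    snr: float = 20.0,
    ramp_y: bool = False,
    seed: int = 0,
    width: float | None = None,
) -> ExperimentCodes:
    """Build the four fixed populations of the integration experiment.

    Input widths default to the total-MSE-optimal width for a K = 2 code of
    the given size and SNR. With ``ramp_y=True``, region Y encodes the
    common feature through a signed linear ramp instead of Gaussian tuning
    (auditory-position-like format).
    """
    if width is None:
        width = rf_code.optimal_width(n_input_units, 2, snr, seed=seed)
    ss = np.random.SeedSequence(seed).generate_state(4)
    pop_x = rf_code.build_population(n_input_units, 2, width, snr, seed=int(ss[0] % 2**31))
    if ramp_y:
        pop_y = rf_code.build_population(
            n_input_units, 2, width, snr, kind="ramp", ramp_dims=(0,), seed=int(ss[1] % 2**31)
        )
    else:
        pop_y = rf_code.build_population(n_input_units, 2, width, snr, seed=int(ss[1] % 2**31))
    pop_int = rf_code.build_population(
        n_integration_units, 3, width, snr, seed=int(ss[2] % 2**31)
    )
    pop_out = rf_code.build_population(n_output_units, 2, width, snr, seed=int(ss[3] % 2**31))
    return ExperimentCodes(pop_x, pop_y, pop_int, pop_out, snr)


def _pair_means(pop: rf_code.RFPopulation, stim_a: np.ndarray, stim_b: np.ndarray) -> np.ndarray:
    """Noiseless two-stimulus responses (sum of the two mean responses)."""
    return rf_code.mean_response(pop, stim_a) + rf_code.mean_response(pop, stim_b)


def generate_trials(codes: ExperimentCodes, n: int, seed, *, noisy_inputs: bool = True) -> dict:
    """Sample a batch of trials.

    Each trial draws two independent uniform K = 3 stimuli
    ``(c, u_x, u_y)``. Inputs are the noisy two-stimulus responses of the
    input populations; the integration and output targets are the noiseless
    two-stimulus responses of the target populations. The swapped output
    target (the prototypical assignment error) exchanges the unique
    features between the two stimuli.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stim = rng.uniform(0.0, 1.0, size=(n, 2, 3))  # (trial, stimulus, feature c/ux/uy)
    a, b = stim[:, 0], stim[:, 1]
    x_in = _pair_means(codes.pop_x, a[:, [0, 1]], b[:, [0, 1]])
    y_in = _pair_means(codes.pop_y, a[:, [0, 2]], b[:, [0, 2]])
    if noisy_inputs:
        x_in = x_in + rng.normal(0.0, codes.pop_x.sigma_N, size=x_in.shape)
        y_in = y_in + rng.normal(0.0, codes.pop_y.sigma_N, size=y_in.shape)
    integ_target = _pair_means(codes.pop_integration, a, b)
    out_target = _pair_means(codes.pop_output, a[:, [1, 2]], b[:, [1, 2]])
    swapped = _pair_means(
        codes.pop_output,
        np.stack([a[:, 1], b[:, 2]], axis=1),
        np.stack([b[:, 1], a[:, 2]], axis=1),
    )
    return {
        "stimuli": stim,
        "inputs": np.concatenate([x_in, y_in], axis=1),
        "integration_target": integ_target,
        "output_target": out_target,
        "swapped_target": swapped,
        "delta_common": np.abs(a[:, 0] - b[:, 0]),
    }


def generate_trial(codes: ExperimentCodes, seed) -> dict:
    """A single trial; see :func:`generate_trials`."""
    batch = generate_trials(codes, 1, seed)
    return {k: v[0] for k, v in batch.items()}


# ---------------------------------------------------------------------------
# a minimal dense ReLU network with Adam


class Network:
    """Dense feedforward net; optional supervised integration layer.

    ``integration_index`` (into the hidden activations) marks the ReLU layer
    whose activity is matched to the integration target when training with
    the dual objective; the final layer is always affine.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        sizes = spec.layer_sizes()
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = math.sqrt(2.0 / fan_in)  # He init for ReLU layers
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.n_layers = len(self.weights)
        if spec.variant == "integration_learning":
            # the integration layer is the last layer before the output head
            self.integration_index = self.n_layers - 2
        else:
            self.integration_index = None

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(self, x: np.ndarray, return_hidden: bool = False):
        acts = []
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = z if i == self.n_layers - 1 else np.maximum(z, 0.0)  # linear head
            acts.append(h)
        return (acts[-1], acts) if return_hidden else acts[-1]

    def loss_and_grads(self, x, out_target, integ_target, w_int, w_out):
        out, acts = self.forward(x, return_hidden=True)
        n = x.shape[0]
        losses = {}
        # output MSE and its gradient at the head
        d_out = out - out_target
        losses["output"] = float(np.mean(d_out**2))
        deltas = [None] * self.n_layers
        deltas[-1] = (2.0 * w_out / (n * out.shape[1])) * d_out
        if self.integration_index is not None and integ_target is not None:
            gi = acts[self.integration_index]
            d_int = gi - integ_target
            losses["integration"] = float(np.mean(d_int**2))
            extra = (2.0 * w_int / (n * gi.shape[1])) * d_int
        else:
            extra = None
        grads_w = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        delta = deltas[-1]
        for i in range(self.n_layers - 1, -1, -1):
            inp = x if i == 0 else acts[i - 1]
            grads_w[i] = inp.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i - 1] > 0)
                if extra is not None and i - 1 == self.integration_index:
                    delta = delta + extra * (acts[i - 1] > 0)
        total = w_out * losses["output"] + w_int * losses.get("integration", 0.0)
        losses["total"] = float(total)
        return losses, grads_w, grads_b


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate one of the four trainable variants."""
    return Network(spec, seed=seed)


def train(
    network: Network,
    codes: ExperimentCodes,
    config: TrainingConfig,
) -> tuple[Network, dict]:
    """Train by Adam on MSE with early stopping.

    The stimulus sample is fixed; input noise is redrawn at every epoch
    (fresh presentations of the same stimuli). Validation uses held-out
    stimuli with fixed noise; training halts when the validation loss fails
    to improve for ``early_stop_patience`` epochs, restoring the best
    weights.
    """
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(config.n_samples * config.val_fraction))
    n_train = config.n_samples - n_val
    clean = generate_trials(codes, n_train, rng, noisy_inputs=False)
    val = generate_trials(codes, n_val, rng, noisy_inputs=True)
    w_int = config.integration_loss_weight if network.integration_index is not None else 0.0
    w_out = config.output_loss_weight
    params = network.weights + network.biases
    opt = _Adam(params, config.learning_rate)

    history = {"train": [], "val": [], "train_output": [], "train_integration": []}
    best_val, best_state, patience = np.inf, None, 0
    sx, sy = codes.pop_x.sigma_N, codes.pop_y.sigma_N
    nx = codes.pop_x.n_units
    for epoch in range(config.max_epochs):
        noise = np.concatenate(
            [
                rng.normal(0.0, sx, size=(n_train, nx)),
                rng.normal(0.0, sy, size=(n_train, codes.pop_y.n_units)),
            ],
            axis=1,
        )
        inputs = clean["inputs"] + noise
        order = rng.permutation(n_train)
        epoch_losses = []
        for lo in range(0, n_train, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            losses, gw, gb = network.loss_and_grads(
                inputs[idx],
                clean["output_target"][idx],
                clean["integration_target"][idx] if w_int else None,
                w_int,
                w_out,
            )
            if not np.isfinite(losses["total"]):
                raise ArithmeticError(f"training diverged at epoch {epoch} (loss NaN/inf)")
            opt.step(params, gw + gb)
            epoch_losses.append(losses)
        history["train"].append(float(np.mean([l["total"] for l in epoch_losses])))
        history["train_output"].append(float(np.mean([l["output"] for l in epoch_losses])))
        if w_int:
            history["train_integration"].append(
                float(np.mean([l["integration"] for l in epoch_losses]))
            )
        val_losses, _, _ = network.loss_and_grads(
            val["inputs"],
            val["output_target"],
            val["integration_target"] if w_int else None,
            w_int,
            w_out,
        )
        history["val"].append(val_losses["total"])
        if val_losses["total"] < best_val - 1e-12:
            best_val = val_losses["total"]
            best_state = ([w.copy() for w in network.weights], [b.copy() for b in network.biases])
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_state is not None:
        network.weights, network.biases = best_state
    history["stopped_epoch"] = epoch + 1
    return network, history


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvalResult:
    bin_edges: np.ndarray
    bin_rates: np.ndarray  # nan where a bin has too few trials
    bin_counts: np.ndarray
    theory_F: np.ndarray  # full-form crossing probability at bin centers
    theory_F_no_product: np.ndarray
    overall_rate: float
    input_local_mse: tuple[float, float]


def _common_feature_mse(codes: ExperimentCodes) -> tuple[float, float]:
    """Local MSE of the common feature in each input population.

    Gaussian codes: 1 / FI from the analytic expression. Ramp codes encode
    the common feature through the linear term; the averaged Fisher
    information is ``(4 n P^2 / sigma^2) E[u^2] A(w)^{K_G} = 12 SNR^2``
    for unit-total power (derivative of ``2P(x_R - 1/2) u`` is ``2 P u``
    times the Gaussian factor).
    """
    out = []
    for pop in (codes.pop_x, codes.pop_y):
        if pop.kind == "gaussian":
            fi, _ = rf_code.fisher_information(pop)
        else:
            n_ramp = len(pop.ramp_dims)
            n_gauss = pop.K - n_ramp
            a = rf_code._bracket_A(pop.w)
            fi = 4.0 * pop.n_units * pop.P**2 / (pop.sigma_N**2 * n_ramp) * a**n_gauss
        out.append(1.0 / fi)
    return tuple(out)


def evaluate_assignment(
    network: Network,
    codes: ExperimentCodes,
    n_trials: int = 20_000,
    n_bins: int = 10,
    seed: int = 0,
    min_bin_trials: int = 200,
) -> EvalResult:
    """Assignment error rate of a (possibly untrained) network.

    A trial errs when the network output is closer (squared distance) to the
    swapped output target than to the correct one. Rates are binned by the
    true common-feature distance; bins with fewer than ``min_bin_trials``
    trials are reported as NaN. The theory curves give the crossing
    probability ``F(delta)`` at the bin centers using the input codes'
    common-feature local MSE as decoder variances.
    """
    trials = generate_trials(codes, n_trials, seed)
    out = network.forward(trials["inputs"])
    d_correct = np.sum((out - trials["output_target"]) ** 2, axis=1)
    d_swap = np.sum((out - trials["swapped_target"]) ** 2, axis=1)
    errors = d_swap < d_correct
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(trials["delta_common"], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    rates = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if counts[b] >= min_bin_trials:
            rates[b] = errors[which == b].mean()
    d_x, d_y = _common_feature_mse(codes)
    noise = NoiseSpec(D_X=d_x, D_Y=d_y)
    centers = 0.5 * (edges[:-1] + edges[1:])
    theory = crossing_probability(centers, noise)
    theory_np = crossing_probability(centers, noise, drop_product_term=True)
    return EvalResult(
        bin_edges=edges,
        bin_rates=rates,
        bin_counts=counts,
        theory_F=np.asarray(theory),
        theory_F_no_product=np.clip(np.asarray(theory_np), 0, 1),
        overall_rate=float(errors.mean()),
        input_local_mse=(d_x, d_y),
    )


DEFAULT_VARIANTS = {
    "end_to_end_direct": NetworkSpec(
        variant="end_to_end", has_hidden=False, has_integration_layer=False
    ),
    "end_to_end_deep": NetworkSpec(
        variant="end_to_end", has_hidden=True, has_integration_layer=True
    ),
    "integration_learning": NetworkSpec(
        variant="integration_learning", has_hidden=False, has_integration_layer=True
    ),
    "integration_learning_hidden": NetworkSpec(
        variant="integration_learning", has_hidden=True, has_integration_layer=True
    ),
}


def run_variant(
    name: str,
    codes: ExperimentCodes,
    config: TrainingConfig,
    n_eval: int = 20_000,
    eval_seed: int | None = None,
) -> tuple[Network, dict, EvalResult]:
    """Build, train and evaluate one named variant."""
    spec = replace(
        DEFAULT_VARIANTS[name],
        n_inputs=codes.pop_x.n_units + codes.pop_y.n_units,
        n_output=codes.pop_output.n_units,
        n_integration=codes.pop_integration.n_units,
    )
    net = build_network(spec, seed=config.seed)
    net, history = train(net, codes, config)
    result = evaluate_assignment(
        net, codes, n_trials=n_eval, seed=config.seed + 7 if eval_seed is None else eval_seed
    )
    return net, history, result


def ramp_input_experiment(
    variant: str = "integration_learning_hidden",
    n_input_units: int = 128,
    snr: float = 20.0,
    config: TrainingConfig | None = None,
    seed: int = 0,
    n_eval: int = 20_000,
) -> EvalResult:
    """The mixed-format experiment: region Y encodes position as a ramp."""
    config = config if config is not None else TrainingConfig(seed=seed)
    codes = make_codes(n_input_units=n_input_units, snr=snr, ramp_y=True, seed=seed)
    _, _, result = run_variant(variant, codes, config, n_eval=n_eval)
    return result
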