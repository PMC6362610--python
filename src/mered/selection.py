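"""QAIC model comparison, Akaike weights, and overdispersion estimation.

QAIC = deviance / c-hat + 2 * np adjusts the likelihood for marginal
overdispersion (c-hat) in the encounter histories; Akaike weights
w_i = exp(-dQAIC_i / 2) / sum_j exp(-dQAIC_j / 2) quantify relative model
support.  c-hat can be supplied directly (e.g. from an external
goodness-of-fit analysis) or estimated here by a median parametric
bootstrap: simulate from the fitted umbrella model, refit, and take the
ratio of the observed deviance to the median bootstrap deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .events import Dataset
from .fitting import FitResult, fit
from .model import ModelStructure
from .simulate import simulate_conditioned_histories


def qaic(deviance: float, n_params: int, chat: float = 1.0) -> float:
    """Quasi-likelihood AIC.  c-hat below 1 is clamped to 1 with a warning."""
    if n_params < 0:
        raise ValidationError("parameter count must be nonnegative")
    if chat < 1.0:
        warnings.warn(f"c-hat = {chat:.3g} < 1 clamped to 1")
        chat = 1.0
    return deviance / chat + 2.0 * n_params


def akaike_weights(delta_qaic: Sequence[float]) -> np.ndarray:
    """Akaike weights from QAIC differences (re-baselined to min 0)."""
    delta = np.asarray(delta_qaic, dtype=float)
    if delta.size == 0:
        raise ValidationError("need at least one model to weight")
    delta = delta - delta.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelTable:
    """Ranked model-comparison table (name, np, deviance, QAIC, dQAIC, weight)."""

    table: pd.DataFrame

    @classmethod
    def from_models(cls, names: Sequence[str], n_params: Sequence[int],
                    deviances: Sequence[float], chat: float = 1.0) -> "ModelTable":
        if not (len(names) == len(n_params) == len(deviances)):
            raise ValidationError("names, n_params and deviances must align")
        q = np.array([qaic(d, k, chat) for d, k in zip(deviances, n_params)])
        delta = q - q.min()
        df = pd.DataFrame({
            "model": list(names),
            "np": list(n_params),
            "deviance": list(deviances),
            "qaic": q,
            "delta_qaic": delta,
            "weight": akaike_weights(delta),
        }).sort_values("qaic", kind="stable", ignore_index=True)
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        df = self.table
        lines = [f"{'model':<40} {'np':>5} {'deviance':>12} {'dQAIC':>8} {'w':>6}"]
        for r in df.itertuples(index=False):
            lines.append(f"{r.model:<40} {r.np:>5d} {r.deviance:>12.2f} "
                         f"{r.delta_qaic:>8.2f} {r.weight:>6.2f}")
        return "\n".join(lines)


@dataclass
class ChatResult:
    """Parametric-bootstrap overdispersion estimate."""

    chat: float
    observed_deviance: float
    bootstrap_deviances: np.ndarray
    n_failed: int
    reliable: bool


def bootstrap_chat(dataset: Dataset, structure: ModelStructure,
                   umbrella_fit: FitResult, *, n_boot: int = 100,
                   seed: int = 0) -> ChatResult:
    """Median parametric-bootstrap estimate of the overdispersion factor.

    Datasets are simulated at the fitted MLE, conditional on the observed
    first-capture occasions, and refitted (one quasi-Newton start at the
    MLE).  c-hat is the observed deviance divided by the median bootstrap
    deviance; under a correctly specified model it is ~1.  Refit failures
    are excluded with their count reported, and the estimate is flagged
    unreliable when more than 20% fail.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    T = dataset.n_occasions
    truth = structure.expand(umbrella_fit.beta, T)
    truth_years = list(dataset.years)
    first = np.repeat([h.first_occasion for h in dataset.histories], dataset.counts)
    rng = np.random.default_rng(seed)
    devs = []
    n_failed = 0
    for _ in range(n_boot):
        sim = simulate_conditioned_histories(first, truth, rng)
        sim = Dataset(truth_years, sim.histories, sim.counts)
        try:
            refit = fit(sim, structure, n_starts=1, seed=int(rng.integers(2**31)),
                        init=umbrella_fit.beta)
        except ConvergenceError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        devs.append(refit.deviance)
    if not devs:
        raise ConvergenceError("every bootstrap refit failed")
    devs = np.asarray(devs)
    chat = float(umbrella_fit.deviance / np.median(devs))
    reliable = n_failed <= 0.2 * n_boot
    if not reliable:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap refits failed; "
                      "c-hat estimate flagged unreliable")
    return ChatResult(chat, umbrella_fit.deviance, devs, n_failed, reliable)
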