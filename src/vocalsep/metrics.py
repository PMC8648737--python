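"""Permutation-max evaluation: SI-SDR, improvement over the mixture, and
downstream identity-classification accuracy.

SI-SDR follows the standard scale-invariant definition: project the estimate
onto the target with the optimal gain ``alpha = s_hat^T s / |s|^2`` and report
the energy ratio of the scaled target to the residual,

    SI-SDR = 10 log10( |alpha s|^2 / |s_hat - alpha s|^2 )  [dB].

A ``strict_printed_form`` mode computes ``-10 log10 |s_hat - s|^2 +
10 log10 |alpha s|^2`` instead; note that form is not scale invariant and is
kept only for comparison.  Metrics over N sources are maximized over the N!
assignments of outputs to targets, mirroring how the training loss is
minimized over permutations.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .dsp import Waveform

__all__ = [
    "si_sdr",
    "perm_max_metric",
    "input_si_sdr",
    "downstream_accuracy",
    "evaluate",
    "EvalReport",
    "PermutationResult",
    "SI_SDR_CAP_DB",
]

SI_SDR_CAP_DB = 60.0


@dataclass(frozen=True)
class PermutationResult:
    sigma: tuple  # sigma[i] = index of the output assigned to target i
    value: float


def _as_samples(w) -> np.ndarray:
    return w.samples if isinstance(w, Waveform) else np.asarray(w, dtype=np.float64)


def si_sdr(estimate, target, cap: float = SI_SDR_CAP_DB,
           strict_printed_form: bool = False) -> float:
    """Scale-invariant signal-to-distortion ratio in dB.

    Returns ``cap`` when the residual is at machine-noise level (a perfect
    rescaled reconstruction) and ``-inf`` when the estimate is orthogonal to
    the target.
    """
    s_hat, s = _as_samples(estimate), _as_samples(target)
    if s_hat.shape != s.shape:
        raise ValueError("estimate and target lengths differ")
    s_energy = float(s @ s)
    if s_energy == 0.0:
        raise ValueError("SI-SDR undefined for an all-zero target")
    alpha = float(s_hat @ s) / s_energy
    if alpha == 0.0:
        return -np.inf
    scaled = alpha * s
    signal_energy = float(scaled @ scaled)
    if strict_printed_form:
        residual_energy = float(np.sum((s_hat - s) ** 2))
    else:
        residual_energy = float(np.sum((s_hat - scaled) ** 2))
    if residual_energy <= np.finfo(float).eps * signal_energy:
        return cap
    return min(10.0 * np.log10(signal_energy / residual_energy), cap)


def perm_max_metric(estimates, targets, m, cap: int = 4) -> PermutationResult:
    """Exact maximum of ``(1/N) sum_i m(estimates[sigma(i)], targets[i])``
    over all N! permutations sigma."""
    n = len(estimates)
    if n != len(targets):
        raise ValueError("estimate and target set sizes differ")
    if n > cap:
        raise ValueError(f"N={n} exceeds the permutation-search cap {cap}")
    pair = np.array([[m(e, t) for t in targets] for e in estimates])  # [est, tgt]
    best_val, best_sigma = -np.inf, None
    for sigma in itertools.permutations(range(n)):
        val = float(np.mean([pair[sigma[i], i] for i in range(n)]))
        if val > best_val:
            best_val, best_sigma = val, sigma
    return PermutationResult(sigma=best_sigma, value=best_val)


def input_si_sdr(mixture, sources, cap: float = SI_SDR_CAP_DB) -> float:
    """Baseline: the mixture itself used as the estimate for every source."""
    return float(np.mean([si_sdr(mixture, s, cap=cap) for s in sources]))


def downstream_accuracy(separated_sets, label_sets, classifier) -> float:
    """Mean over mixtures of the permutation-max fraction of separated
    outputs the identity classifier labels correctly."""
    scores = []
    for estimates, labels in zip(separated_sets, label_sets):
        predictions = [int(np.argmax(classifier.classify(e).log_probs)) for e in estimates]

        def hit(e_idx, l_idx, preds=predictions, labs=labels):
            return float(preds[e_idx] == labs[l_idx])

        n = len(estimates)
        result = perm_max_metric(list(range(n)), list(range(n)), hit)
        scores.append(result.value)
    return float(np.mean(scores))


@dataclass
class EvalReport:
    si_sdr: float  # dB, permutation-max mean over sources, averaged over mixtures
    input_si_sdr: float  # dB, mixture-as-estimate baseline
    delta_si_sdr: float  # si_sdr - input_si_sdr
    downstream_accuracy: float | None  # fraction, absent in the open regime
    n_mixtures: int
    per_example: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "si_sdr_db": self.si_sdr,
            "input_si_sdr_db": self.input_si_sdr,
            "delta_si_sdr_db": self.delta_si_sdr,
            "downstream_accuracy": self.downstream_accuracy,
            "n_mixtures": self.n_mixtures,
            "per_example": self.per_example,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(model, dataset, classifier=None, cap: float = SI_SDR_CAP_DB) -> EvalReport:
    """Aggregate permutation-max SI-SDR, its improvement over the mixture
    baseline, and (when a classifier is given) downstream accuracy.

    ``model`` needs a ``separate(waveform) -> list[Waveform]`` method; when
    the dataset carries filtered targets (denoising variant) those are the
    references.
    """
    sdr_vals, base_vals, records = [], [], []
    separated_sets, label_sets = [], []
    known = set(range(classifier.config.V)) if classifier is not None else None
    labels_in_range = True
    for ex in dataset:
        estimates = model.separate(ex.mixture)
        refs = ex.training_targets
        result = perm_max_metric(estimates, refs, lambda e, t: si_sdr(e, t, cap=cap))
        base = input_si_sdr(ex.mixture, refs, cap=cap)
        sdr_vals.append(result.value)
        base_vals.append(base)
        records.append({
            "si_sdr_db": result.value,
            "input_si_sdr_db": base,
            "sigma": list(result.sigma),
            "labels": list(ex.labels),
        })
        if classifier is not None:
            if not set(ex.labels) <= known:
                labels_in_range = False
            separated_sets.append(estimates)
            label_sets.append(ex.labels)
    acc = None
    if classifier is not None and labels_in_range:
        acc = downstream_accuracy(separated_sets, label_sets, classifier)
    mean_sdr = float(np.mean(sdr_vals))
    mean_base = float(np.mean(base_vals))
    return EvalReport(
        si_sdr=mean_sdr,
        input_si_sdr=mean_base,
        delta_si_sdr=mean_sdr - mean_base,
        downstream_accuracy=acc,
        n_mixtures=len(dataset),
        per_example=records,
    )
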