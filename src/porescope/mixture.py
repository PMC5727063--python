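"""Mixture counting: classify unlabeled pulses from a mixed sample and
report the assigned-class ratio r_B versus the nominal concentration
ratio C_B.

A classifier trained on single-species teacher data is applied to every
pulse of a mixed recording; r_B = N_B / N_E is the number of pulses
assigned to class B relative to class E.  With equal per-species
capture rates and an accurate classifier the expected r_B tracks C_B;
unequal capture rates (stiffer-walled species enter the pore less
readily) bend the curve sublinearly, which the generator models through
per-class rate multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MixtureResult", "classify_mixture", "sweep_concentrations",
           "expected_assigned_ratio"]


@dataclass
class MixtureResult:
    """Counts and ratio for one mixture classification."""

    c_b: float
    n_assigned: dict[str, int]
    r_b: float
    infinite: bool = False           # flagged when N_E = 0
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.n_assigned.values())


def classify_mixture(X, model, label_e: str, label_b: str,
                     c_b: float = float("nan"), feature_spec: str = "",
                     model_spec: str | None = None, seed: int | None = None
                     ) -> MixtureResult:
    """Assign every pulse exactly one label and compute r_B = N_B / N_E.

    ``feature_spec`` names the feature vector the rows of ``X`` were
    built from and must match the spec the model was trained on when
    the model declares one (``model_spec``).
    """
    if model_spec is not None and feature_spec != model_spec:
        raise ValueError(
            f"feature spec {feature_spec!r} does not match the model's "
            f"training spec {model_spec!r}"
        )
    pred = np.asarray(model.predict(np.asarray(X, dtype=float)))
    n_b = int(np.sum(pred == label_b))
    n_e = int(np.sum(pred == label_e))
    other = len(pred) - n_b - n_e
    if other:
        raise ValueError(f"{other} pulses were assigned to neither class")
    infinite = n_e == 0
    r_b = float("inf") if infinite else n_b / n_e
    return MixtureResult(
        c_b=c_b, n_assigned={label_e: n_e, label_b: n_b}, r_b=r_b,
        infinite=infinite, seed=seed,
        provenance={"feature_spec": feature_spec, "model": type(model).__name__},
    )


def sweep_concentrations(c_b_values, generator, model, label_e: str,
                         label_b: str, n_total: int, seed: int = 0,
                         feature_spec: str = "", model_spec: str | None = None
                         ) -> list[MixtureResult]:
    """Classify generated mixtures over a ladder of concentration ratios.

    ``generator(c_b, n_total, seed)`` must return ``(X, hidden_labels)``
    — e.g. a closure over :func:`porescope.pulse_sim.generate_mixture`
    plus detection/featurization, or a resampler over a labeled pulse
    pool.  One derived seed per C_B is recorded in the results.
    """
    results = []
    root = np.random.SeedSequence(seed)
    for c_b, child in zip(c_b_values, root.spawn(max(len(list(c_b_values)), 1))):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        X, hidden = generator(c_b, n_total, sub_seed)
        res = classify_mixture(X, model, label_e, label_b, c_b=c_b,
                               feature_spec=feature_spec, model_spec=model_spec,
                               seed=sub_seed)
        res.provenance["n_true"] = {
            label_e: int(sum(1 for h in hidden if h == label_e)),
            label_b: int(sum(1 for h in hidden if h == label_b)),
        }
        results.append(res)
    return results


def expected_assigned_ratio(rho: float, epsilon: float) -> float:
    """Expected assigned-count ratio under symmetric per-class error.

    With true ratio ``rho = N_B/N_E`` and symmetric misclassification
    probability ``epsilon``, the expected ratio of assigned counts is
    (rho (1-eps) + eps) / (rho eps + (1-eps)).
    """
    if not (0 <= epsilon <= 1):
        raise ValueError("epsilon must lie in [0, 1]")
    return (rho * (1 - epsilon) + epsilon) / (rho * epsilon + (1 - epsilon))
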