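"""Shared container for fitted-model output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FitResult:
    """Estimates and uncertainty for any of the model families.

    ``estimates``/``se`` are Series indexed by ``part:term`` labels, e.g.
    ``incidence:intercept`` or ``latency:exposure``.  ``diagnostics`` carries
    convergence detail (iterations, gradient norm, EM log-likelihood trace,
    bootstrap failure counts, ...).
    """

    model: str
    estimates: pd.Series
    se: pd.Series
    loglik: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # baselines, weights, params objects

    @property
    def n_params(self) -> int:
        return len(self.estimates)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals: estimate ± z * SE."""
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"lower": self.estimates - z * self.se, "upper": self.estimates + z * self.se}
        )

    def tidy(self) -> pd.DataFrame:
        parts, terms = [], []
        for label in self.estimates.index:
            part, _, term = str(label).partition(":")
            parts.append(part)
            terms.append(term or part)
        return pd.DataFrame(
            {"model": self.model, "part": parts, "term": terms,
             "estimate": self.estimates.to_numpy(),
             "se": self.se.reindex(self.estimates.index).to_numpy()}
        )
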