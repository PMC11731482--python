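"""AIC backward selection over model terms.

Generic engine shared by the longitudinal mixed models and the risk models:
the fitter is any callable mapping a list of terms to a fitted object exposing
``.aic``.  At each step the single candidate whose removal most lowers AIC is
dropped; locked terms are never dropped; the elimination trace is returned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SelectionResult", "aic_backward_select"]


@dataclass
class SelectionResult:
    terms: list
    fit: object
    aic: float
    trace: list = field(default_factory=list)   # (dropped_term, aic_after)


def aic_backward_select(fit_fn, candidates, locked=()) -> SelectionResult:
    """Iteratively drop the candidate whose removal most lowers AIC.

    ``fit_fn(terms)`` must return a fitted object with an ``aic`` attribute;
    exceptions for a candidate removal are treated as an inadmissible drop.
    The full model must fit (exceptions propagate).
    """
    locked = list(locked)
    current = list(candidates)
    fit = fit_fn(locked + current)
    aic = fit.aic
    trace = [(None, aic)]
    while current:
        best = None
        for term in current:
            trial = [t for t in current if t != term]
            try:
                f = fit_fn(locked + trial)
            except Exception:
                continue
            if best is None or f.aic < best[1]:
                best = (term, f.aic, f, trial)
        if best is None or best[1] >= aic:
            break
        term, aic, fit, current = best[0], best[1], best[2], best[3]
        trace.append((term, aic))
    return SelectionResult(terms=locked + current, fit=fit, aic=aic, trace=trace)
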