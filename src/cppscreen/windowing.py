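"""Prime-based windowing of variable-length per-speaker CPP streams.

Speakers contribute CPP streams of different lengths, but the downstream
classifiers need fixed-width feature rows. Each speaker's stream is cut into
consecutive, non-overlapping subgroups of a common prime size ``nprime``;
the tail that does not fill a subgroup is discarded. ``nprime`` is chosen
among the primes in ``[3, nmin]`` (``nmin`` = the smallest per-speaker
count) to minimize the total number of discarded samples, i.e.
``sum_i (count_i mod p)``. Ties are broken toward the larger prime (richer
feature rows per sample).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd
from sympy import primerange

from .dataset import Cohort, WindowedTable, windowed_columns
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowingPlan:
    """The selected subgroup size plus the audit trail of the selection."""

    nprime: int
    nmin: int
    candidates: tuple[int, ...]
    loss_by_candidate: dict[int, int]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "nmin": self.nmin,
                "candidates": list(self.candidates),
                "loss_by_candidate": {str(p): v for p, v in self.loss_by_candidate.items()},
                "nprime": self.nprime,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def candidate_primes(nmin: int) -> list[int]:
    """All primes p with 3 <= p <= nmin, ascending."""
    if nmin < 3:
        raise ValidationError(
            f"cohort too small to window: the minimum per-speaker count is "
            f"{nmin}, but at least 3 CPP values per speaker are required"
        )
    return list(primerange(3, nmin + 1))


def total_loss(counts, p: int) -> int:
    """Total samples discarded when every stream is cut into groups of size p."""
    counts = list(counts)
    if any(c < 1 for c in counts):
        raise ValidationError("per-speaker counts must all be >= 1")
    return int(sum(c % p for c in counts))


def select_nprime(counts) -> WindowingPlan:
    """Choose the prime subgroup size minimizing total discarded samples."""
    counts = list(counts)
    nmin = min(counts)
    candidates = candidate_primes(nmin)
    losses = {p: total_loss(counts, p) for p in candidates}
    best = min(losses.values())
    minimizers = [p for p, v in losses.items() if v == best]
    nprime = max(minimizers)
    if len(minimizers) > 1:
        logger.info(
            "windowing tie among primes %s at loss %d; choosing the larger, %d",
            minimizers,
            best,
            nprime,
        )
    return WindowingPlan(
        nprime=nprime,
        nmin=nmin,
        candidates=tuple(candidates),
        loss_by_candidate=losses,
    )


def apply_windowing(cohort: Cohort, plan: WindowingPlan | int) -> WindowedTable:
    """Cut each speaker's stream into subgroups of size ``nprime``.

    A speaker with ``s`` values yields ``floor(s / nprime)`` rows named
    ``<speaker_id>.<k>`` (k from 1), taking values in original order; the
    final ``s mod nprime`` values are discarded.
    """
    nprime = plan.nprime if isinstance(plan, WindowingPlan) else int(plan)
    if nprime > min(cohort.counts):
        raise ValidationError(
            f"nprime={nprime} exceeds the smallest per-speaker count "
            f"({min(cohort.counts)})"
        )
    rows = []
    for record in cohort:
        n_groups = record.n_values // nprime
        for k in range(1, n_groups + 1):
            chunk = record.cpp_values[(k - 1) * nprime : k * nprime]
            row = {"Name": f"{record.speaker_id}.{k}"}
            row.update({f"CPP{i + 1}": chunk[i] for i in range(nprime)})
            row.update({"Target": record.label, "Sex": record.sex, "Group": record.age_group})
            rows.append(row)
    data = pd.DataFrame(rows, columns=windowed_columns(nprime))
    return WindowedTable(data=data, nprime=nprime)


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class PrimeWindower(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: ``fit`` selects the prime subgroup size
    from a cohort's per-speaker counts, ``transform`` windows the cohort.

    Parameters
    ----------
    nprime : int or None
        Force a subgroup size instead of minimizing the discarded-sample
        count (e.g. 7 to mirror a reference analysis). When None the size
        is selected at fit time.

    Attributes
    ----------
    plan_ : WindowingPlan
        Selection audit (nmin, candidate primes, per-candidate loss).
    nprime_ : int
        The subgroup size actually used.
    """

    def __init__(self, nprime: int | None = None) -> None:
        self.nprime = nprime

    def fit(self, X: Cohort, y=None) -> "PrimeWindower":
        plan = select_nprime(X.counts)
        if self.nprime is not None:
            losses = dict(plan.loss_by_candidate)
            losses.setdefault(int(self.nprime), total_loss(X.counts, int(self.nprime)))
            plan = WindowingPlan(
                nprime=int(self.nprime),
                nmin=plan.nmin,
                candidates=plan.candidates,
                loss_by_candidate=losses,
            )
        self.plan_ = plan
        self.nprime_ = plan.nprime
        return self

    def transform(self, X: Cohort) -> WindowedTable:
        return apply_windowing(X, self.nprime_)
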