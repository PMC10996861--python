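"""Leave-one-speaker-out evaluation with repeated iterations and pairwise
rank-sum method comparison.

Protocol: every fold holds out all windowed rows of one speaker as the
validation set and trains on everyone else, so no subgroup of a speaker can
leak across the split. Each fold is repeated for ``n_iterations`` seeds; when
SMOTE is enabled (case study 2) a freshly augmented training set is generated
per iteration, so per-speaker accuracies fluctuate across iterations. Without
SMOTE (case study 1) deterministic models yield identical iterations.

Per speaker, the two 10-value accuracy vectors of any two methods are
compared with the two-sided Wilcoxon rank-sum (Mann-Whitney U) test; when all
values of both vectors are one identical constant the test is undefined and
reported as NA — the convention behind all-NA rows at uniform 100 % accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .augmentation import SYNTHETIC_FLAG, SmoteConfig, balance_training_fold
from .classifiers import CANONICAL_ORDER, ModelSpec, fit, predict
from .dataset import WindowedTable
from .exceptions import ValidationError

#: two-sided significance threshold for the pairwise comparison tables
SIGNIFICANCE_LEVEL = 0.05

#: largest combined sample size for exact rank-sum enumeration
EXACT_ENUMERATION_MAX_N = 20


# ---------------------------------------------------------------------------
# Rank-sum (Mann-Whitney U) test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    """U statistic, two-sided p (None when undefined), sizes and rank sum."""

    u_statistic: float
    p_value: float | None
    n1: int
    n2: int
    sum_ranks_1: float

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value <= SIGNIFICANCE_LEVEL


def _exact_rank_sum_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of subsets of size n1 of ranks 1..n1+n2 by rank sum.

    Index w of the returned array is the rank-sum offset from the minimum
    n1(n1+1)/2; standard dynamic program over U = W - min(W) in [0, n1*n2].
    """
    # f_k(u): ways to pick k ranks with U-offset u; add ranks one at a time
    f = [np.zeros(n1 * n2 + 1) for _ in range(n1 + 1)]
    f[0][0] = 1.0
    for rank in range(1, n1 + n2 + 1):
        for k in range(min(rank, n1), 0, -1):
            # picking `rank` as the k-th smallest adds rank - k to the offset
            shift = rank - k
            if shift <= n1 * n2:
                f[k][shift:] += f[k - 1][: n1 * n2 + 1 - shift]
    return f[n1]


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney U test.

    Midranks for ties; ``U = sum(ranks of x) - n1(n1+1)/2``. The p-value is
    exact (full enumeration of rank assignments) for tie-free samples with
    ``n1 + n2 <= 20``, otherwise a tie- and continuity-corrected normal
    approximation. When every element of both samples is one identical
    constant no ordering information exists and the p-value is None (NA).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    sum_ranks_1 = float(ranks[:n1].sum())
    u = sum_ranks_1 - n1 * (n1 + 1) / 2.0

    if np.ptp(pooled) == 0:
        return RankSumResult(u, None, n1, n2, sum_ranks_1)

    has_ties = np.unique(pooled).size < pooled.size
    mu = n1 * n2 / 2.0
    if not has_ties and n1 + n2 <= EXACT_ENUMERATION_MAX_N:
        dist = _exact_rank_sum_distribution(n1, n2)
        dev = abs(u - mu)
        support = np.arange(dist.size)
        p = dist[np.abs(support - mu) >= dev - 1e-9].sum() / comb(n1 + n2, n1)
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return RankSumResult(u, None, n1, n2, sum_ranks_1)
        z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return RankSumResult(u, float(min(p, 1.0)), n1, n2, sum_ranks_1)


# ---------------------------------------------------------------------------
# LOSO protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseStudyConfig:
    """One case study: SMOTE on/off, iteration seeds, and the model roster."""

    model_specs: tuple
    use_smote: bool = False
    n_iterations: int = 10
    seeds: tuple[int, ...] | None = None
    smote: SmoteConfig = field(default_factory=SmoteConfig)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        seeds = self.seeds
        if seeds is None:
            seeds = tuple(range(self.n_iterations))
            object.__setattr__(self, "seeds", seeds)
        if len(seeds) != self.n_iterations or len(set(seeds)) != len(seeds):
            raise ValidationError(
                f"need {self.n_iterations} distinct seeds, got {seeds}"
            )
        object.__setattr__(self, "model_specs", tuple(self.model_specs))
        if not self.model_specs:
            raise ValidationError("at least one model spec is required")


def loso_folds(table: WindowedTable):
    """One (train_rows, validation_rows, speaker_id) triple per speaker."""
    speakers = table.speaker_ids()
    if len(speakers) < 2:
        raise ValidationError("leave-one-speaker-out requires at least 2 speakers")
    row_speaker = table.speaker_of_rows()
    folds = []
    for speaker in speakers:
        mask = row_speaker == speaker
        train = table.data[~mask]
        val = table.data[mask]
        if train["Target"].nunique() < 2:
            raise ValidationError(
                f"holding out speaker {speaker!r} leaves a single-class training set"
            )
        folds.append((train, val, speaker))
    return folds


@dataclass
class EvaluationReport:
    """Per-speaker x per-iteration accuracies for each method."""

    speaker_ids: list[str]
    methods: list[str]
    accuracy: dict[str, np.ndarray]  # method -> (n_speakers, n_iterations)
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        shape = (len(self.speaker_ids), len(self.seeds))
        for method, matrix in self.accuracy.items():
            if matrix.shape != shape:
                raise ValidationError(
                    f"{method}: accuracy matrix shape {matrix.shape} != {shape}"
                )
            if np.any((matrix < 0) | (matrix > 1)):
                raise ValidationError(f"{method}: accuracies outside [0, 1]")

    @property
    def n_iterations(self) -> int:
        return len(self.seeds)

    def per_speaker_stats(self) -> pd.DataFrame:
        """Mean and sample sd over iterations, per speaker and method."""
        frames = {}
        for method in self.methods:
            m = self.accuracy[method]
            frames[(method, "mean")] = m.mean(axis=1)
            frames[(method, "sd")] = m.std(axis=1, ddof=1) if m.shape[1] > 1 else np.zeros(m.shape[0])
        return pd.DataFrame(frames, index=self.speaker_ids)

    def overall_mean(self) -> dict[str, float]:
        """Per method: mean over speakers of the per-speaker iteration means."""
        return {m: float(self.accuracy[m].mean(axis=1).mean()) for m in self.methods}


def _ordered_methods(methods) -> list[str]:
    key = {m: i for i, m in enumerate(CANONICAL_ORDER)}
    return sorted(methods, key=lambda m: key.get(m, len(key)))


def run_case_study(table: WindowedTable, cfg: CaseStudyConfig) -> EvaluationReport:
    """Run the LOSO protocol for every model spec and iteration seed."""
    folds = loso_folds(table)
    feature_cols = table.feature_columns
    methods = [spec.method for spec in cfg.model_specs]
    if len(set(methods)) != len(methods):
        raise ValidationError("duplicate methods in the model roster")
    speakers = [speaker for _, _, speaker in folds]
    accuracy = {m: np.zeros((len(folds), cfg.n_iterations)) for m in methods}

    for it, seed in enumerate(cfg.seeds):
        for fold_idx, (train, val, _) in enumerate(folds):
            if cfg.use_smote:
                fold_seed = (int(seed) * 100_003 + fold_idx * 7_919 + 1) % 2**31
                augmented = balance_training_fold(
                    train,
                    SmoteConfig(cfg.smote.k_neighbors, cfg.smote.target_ratio, fold_seed),
                )
            else:
                augmented = train
            X_train = augmented[feature_cols].to_numpy(dtype=float)
            y_train = augmented["Target"].to_numpy()
            if SYNTHETIC_FLAG in val.columns and val[SYNTHETIC_FLAG].any():
                raise ValidationError("synthetic rows must never reach a validation set")
            X_val = val[feature_cols].to_numpy(dtype=float)
            y_val = val["Target"].to_numpy()
            for spec in cfg.model_specs:
                model = fit(spec, X_train, y_train)
                accuracy[spec.method][fold_idx, it] = float(
                    np.mean(predict(model, X_val) == y_val)
                )
    return EvaluationReport(
        speaker_ids=speakers,
        methods=_ordered_methods(methods),
        accuracy=accuracy,
        seeds=tuple(cfg.seeds),
    )


def comparison_table(report: EvaluationReport) -> pd.DataFrame:
    """Per-speaker pairwise rank-sum p-values over the iteration vectors.

    Columns follow the conventional pair order (e.g. RF_vs_SVM ... KNN_vs_LDA
    for the full roster); undefined tests are None (rendered "NA").
    """
    methods = _ordered_methods(report.methods)
    if len(methods) < 2:
        raise ValidationError("comparison requires at least 2 methods")
    pairs = list(combinations(methods, 2))
    columns = [f"{a.upper()}_vs_{b.upper()}" for a, b in pairs]
    rows = []
    for i, _speaker in enumerate(report.speaker_ids):
        row = {}
        for (a, b), col in zip(pairs, columns):
            result = rank_sum_test(report.accuracy[a][i], report.accuracy[b][i])
            row[col] = result.p_value
        rows.append(row)
    # object dtype keeps the None (NA) entries distinct from numeric values
    return pd.DataFrame(rows, index=report.speaker_ids, columns=columns, dtype=object)


def summarize(report: EvaluationReport) -> dict:
    """Overall per-method means plus per-speaker mean ± sd."""
    return {
        "overall_mean": report.overall_mean(),
        "per_speaker": report.per_speaker_stats(),
    }


# ---------------------------------------------------------------------------
# Report writers (accuracy and comparison tables as CSV)
# ---------------------------------------------------------------------------


def format_percent(fraction: float, decimals: int) -> str:
    return f"{100.0 * fraction:.{decimals}f}%"


def write_accuracy_csv(report: EvaluationReport, path) -> None:
    """Per-speaker mean accuracy per method (two decimals) with a final
    overall-mean row (one decimal)."""
    methods = _ordered_methods(report.methods)
    stats = report.per_speaker_stats()
    overall = report.overall_mean()
    rows = []
    for speaker in report.speaker_ids:
        row = {"Speaker": speaker}
        for m in methods:
            row[m.upper()] = format_percent(stats.loc[speaker, (m, "mean")], 2)
        rows.append(row)
    rows.append(
        {"Speaker": "Overall", **{m.upper(): format_percent(overall[m], 1) for m in methods}}
    )
    pd.DataFrame(rows, columns=["Speaker"] + [m.upper() for m in methods]).to_csv(
        path, index=False
    )


def write_comparison_csv(report: EvaluationReport, path) -> None:
    """Pairwise p-value table, literal ``NA`` for undefined tests."""
    table = comparison_table(report)
    out = table.map(lambda p: "NA" if p is None or pd.isna(p) else f"{p:.3f}")
    out.insert(0, "Speaker", table.index)
    out.to_csv(path, index=False)
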