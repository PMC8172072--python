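"""Monte Carlo cross-validation model selection.

Candidates compete over repeated random 80/20 splits of the cohort-level
observations: each run fits every candidate on the training 80% and scores
it by RMSE on the held-out 20%; the run's winner is the minimum-RMSE
candidate. Aggregated over (by default) 1000 runs, the optimal model is
the one most frequently best — a plurality, not necessarily a majority,
since closely related term sets split wins among themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import (
    CandidateModel,
    DEFAULT_C_GRID,
    design_matrix,
    exponential_year_trend,
    make_model,
    profile_exponential_fit,
    response_vector,
)


@dataclass
class CVConfig:
    train_fraction: float = 0.8
    n_runs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def split(n_or_obs, train_fraction: float, rng: np.random.Generator):
    """Random disjoint train/test partition; |train| = round(f * n)."""
    n = n_or_obs if isinstance(n_or_obs, (int, np.integer)) else len(n_or_obs)
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"cannot split {n} rows at fraction {train_fraction}")
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def rmse(predicted, observed) -> float:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must have equal non-zero length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class RankingTable:
    """Per-candidate frequency of being the run winner."""

    table: pd.DataFrame  # candidate_id, outcome, family, n_params, wins, win_frequency
    n_runs: int
    n_void: int
    winner_log: pd.DataFrame = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        self.table[
            ["candidate_id", "family", "outcome", "wins", "win_frequency"]
        ].to_csv(path, index=False)


class SelectionError(RuntimeError):
    pass


def select_optimal(ranking: RankingTable) -> CandidateModel:
    """Highest win frequency; ties broken by fewest parameters, then id."""
    if ranking.n_runs - ranking.n_void < 1:
        raise SelectionError("every cross-validation run was void")
    t = ranking.table.sort_values(
        ["wins", "n_params", "candidate_id"], ascending=[False, True, True]
    )
    return t.iloc[0]["candidate"]


class MCCVSelector(BaseEstimator):
    """Model selector over repeated random splits, scikit-learn style.

    Parameters
    ----------
    candidates : list of CandidateModel sharing one outcome.
    train_fraction, n_runs, random_state : the Monte Carlo CV plan.
    c_grid : profiled-rate grid for exponential-family fits in the inner
        loop (the winning candidate is refit with the full optimiser).

    Fitted attributes: ``ranking_`` (RankingTable), ``best_candidate_``,
    and ``best_model_`` — the optimal candidate refitted on all data.
    """

    def __init__(
        self,
        candidates: Sequence[CandidateModel] = (),
        train_fraction: float = 0.8,
        n_runs: int = 1000,
        random_state: int = 0,
        c_grid=DEFAULT_C_GRID,
    ):
        self.candidates = candidates
        self.train_fraction = train_fraction
        self.n_runs = n_runs
        self.random_state = random_state
        self.c_grid = c_grid

    def fit(self, X: pd.DataFrame, y=None):
        cands = list(self.candidates)
        if not cands:
            raise ValueError("no candidates to select among")
        outcomes = {c.outcome for c in cands}
        if len(outcomes) != 1:
            raise ValueError("all candidates must share one outcome")
        cfg = CVConfig(self.train_fraction, self.n_runs, self.random_state)
        y_full = response_vector(cands[0], X) if y is None else np.asarray(y, float)
        year_c = np.asarray(X["year_c"], dtype=float)
        designs = [design_matrix(c, X)[0] for c in cands]
        n = y_full.size
        max_p = max(c.n_params for c in cands)
        if int(round(cfg.train_fraction * n)) <= max_p:
            raise ValueError("training split smaller than the largest candidate")

        rng = np.random.default_rng(cfg.seed)
        wins = np.zeros(len(cands), dtype=int)
        n_void = 0
        log_rows = []
        for run in range(cfg.n_runs):
            tr, te = split(n, cfg.train_fraction, rng)
            scores = np.full(len(cands), np.inf)
            for j, cand in enumerate(cands):
                Xl = designs[j]
                try:
                    if cand.family == "linear":
                        beta, _, rank, _ = np.linalg.lstsq(
                            Xl[tr], y_full[tr], rcond=None
                        )
                        if rank < Xl.shape[1]:
                            continue
                        pred = Xl[te] @ beta
                    else:
                        theta, _ = profile_exponential_fit(
                            year_c[tr], Xl[tr], y_full[tr], self.c_grid
                        )
                        pred = exponential_year_trend(
                            theta[0], theta[1], theta[2], year_c[te]
                        )
                        if Xl.shape[1]:
                            pred = pred + Xl[te] @ theta[3:]
                    scores[j] = rmse(pred, y_full[te])
                except Exception:  # noqa: BLE001 - failed fit scores +inf
                    continue
            if not np.any(np.isfinite(scores)):
                n_void += 1
                warnings.warn(f"run {run}: every candidate failed", stacklevel=2)
                continue
            w = int(np.argmin(scores))
            wins[w] += 1
            log_rows.append(
                {"run": run, "winner_id": cands[w].id, "rmse": float(scores[w])}
            )

        denom = max(cfg.n_runs - n_void, 1)
        table = pd.DataFrame(
            {
                "candidate_id": [c.id for c in cands],
                "outcome": [c.outcome for c in cands],
                "family": [c.family for c in cands],
                "n_params": [c.n_params for c in cands],
                "wins": wins,
                "win_frequency": wins / denom,
                "candidate": cands,
            }
        ).sort_values(["wins", "n_params", "candidate_id"], ascending=[False, True, True]).reset_index(drop=True)
        self.ranking_ = RankingTable(
            table=table,
            n_runs=cfg.n_runs,
            n_void=n_void,
            winner_log=pd.DataFrame(log_rows),
        )
        self.best_candidate_ = select_optimal(self.ranking_)
        self.best_model_ = make_model(self.best_candidate_).fit(X)
        return self


def run_mccv(
    candidates: Sequence[CandidateModel],
    observations: pd.DataFrame,
    cv_config: CVConfig | None = None,
) -> RankingTable:
    """Functional wrapper over MCCVSelector returning the ranking table."""
    cfg = cv_config or CVConfig()
    sel = MCCVSelector(
        candidates,
        train_fraction=cfg.train_fraction,
        n_runs=cfg.n_runs,
        random_state=cfg.seed,
    ).fit(observations)
    return sel.ranking_
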