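"""Round-robin tournament aggregation: league tables, pairwise matrices,
and goal-difference statistics.

League scoring follows the standard human-soccer convention: 3 points for a
win, 1 for a tie, 0 for a loss. A team's *average goal difference* — the
mean over its games of goals scored minus goals conceded — measures the
magnitude of its success; league points measure its consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MatchResult

__all__ = [
    "league_points",
    "build_league",
    "pairwise_matrices",
    "goal_difference_anova",
    "AnovaResult",
]


def league_points(wins: int, ties: int) -> int:
    """League points from a win/tie record: 3 per win, 1 per tie, 0 per loss."""
    if wins < 0 or ties < 0:
        raise ValueError("win and tie counts must be non-negative")
    return 3 * wins + ties


def _per_team_games(ledger: Sequence[MatchResult]) -> pd.DataFrame:
    """One row per (team, game): goals scored/conceded and the opponent."""
    rows = []
    for m in ledger:
        rows.append((m.team_a, m.team_b, m.goals_a, m.goals_b))
        rows.append((m.team_b, m.team_a, m.goals_b, m.goals_a))
    df = pd.DataFrame(rows, columns=["team", "opponent", "scored", "conceded"])
    # canonical row order makes every aggregate exactly permutation-invariant
    return df.sort_values(
        by=["team", "opponent", "scored", "conceded"],
        kind="mergesort",
        ignore_index=True,
    )


def build_league(ledger: Sequence[MatchResult]) -> pd.DataFrame:
    """Aggregate a match ledger into a league table.

    Returns a DataFrame indexed by team with columns ``league_points, wins,
    losses, ties, games, goals_scored_mean, goals_scored_se,
    goals_conceded_mean, goals_conceded_se, avg_goal_difference``, sorted by
    points (ties broken by average goal difference, then name). Invariant:
    points = 3*wins + ties and wins + losses + ties = games for every row.
    """
    if not ledger:
        raise ValueError("ledger is empty")
    g = _per_team_games(ledger)
    g["win"] = g["scored"] > g["conceded"]
    g["loss"] = g["scored"] < g["conceded"]
    g["tie"] = g["scored"] == g["conceded"]
    g["diff"] = g["scored"] - g["conceded"]

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    table = g.groupby("team").agg(
        wins=("win", "sum"),
        losses=("loss", "sum"),
        ties=("tie", "sum"),
        games=("win", "size"),
        goals_scored_mean=("scored", "mean"),
        goals_scored_se=("scored", _se),
        goals_conceded_mean=("conceded", "mean"),
        goals_conceded_se=("conceded", _se),
        avg_goal_difference=("diff", "mean"),
    )
    table.insert(
        0, "league_points", (3 * table["wins"] + table["ties"]).astype(int)
    )
    table = table.sort_values(
        by=["league_points", "avg_goal_difference", "team"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return table


def pairwise_matrices(
    ledger: Sequence[MatchResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Win matrix and mean-goals matrix over all team pairs.

    ``wins.loc[i, j]`` counts games i beat j (ties excluded);
    ``goals.loc[i, j]`` is the mean goals i scored against j, NaN where the
    pair never met. Neither matrix is symmetric in general.
    """
    g = _per_team_games(ledger)
    teams = sorted(set(g["team"]))
    wins = pd.DataFrame(0, index=teams, columns=teams, dtype=int)
    won = g[g["scored"] > g["conceded"]].groupby(["team", "opponent"]).size()
    for (ti, tj), n in won.items():
        wins.loc[ti, tj] = int(n)
    goals = pd.DataFrame(np.nan, index=teams, columns=teams, dtype=float)
    means = g.groupby(["team", "opponent"])["scored"].mean()
    for (ti, tj), m in means.items():
        goals.loc[ti, tj] = float(m)
    return wins, goals


@dataclass
class AnovaResult:
    """One-way ANOVA on per-game goal difference, plus Bonferroni-adjusted
    pairwise comparisons (pooled-variance two-sample t tests)."""

    f: float
    p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # team_a, team_b, mean_diff, t, p_raw, p_bonf
    degenerate: bool = False


def goal_difference_anova(
    ledger: Sequence[MatchResult], *, equal_var: bool = True
) -> AnovaResult:
    """Test whether teams differ in average per-game goal difference.

    Each team contributes one observation per game (goals scored minus
    conceded in that game). Pairwise comparisons use two-sample t tests
    (pooled variance by default, Welch with ``equal_var=False``) with
    Bonferroni adjustment over all k(k-1)/2 pairs. If every group has zero
    variance the result is flagged degenerate (F undefined).
    """
    g = _per_team_games(ledger)
    g["diff"] = g["scored"] - g["conceded"]
    groups = {team: sub["diff"].to_numpy(float) for team, sub in g.groupby("team")}
    teams = sorted(groups)
    if len(teams) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 teams with >= 2 games each")

    samples = [groups[t] for t in teams]
    degenerate = all(np.var(s) == 0 for s in samples)
    if degenerate:
        f_stat, p_val = np.nan, np.nan
    else:
        f_stat, p_val = stats.f_oneway(*samples)

    m = len(teams) * (len(teams) - 1) // 2
    rows = []
    for i in range(len(teams)):
        for j in range(i + 1, len(teams)):
            a, b = groups[teams[i]], groups[teams[j]]
            if np.var(a) == 0 and np.var(b) == 0:
                t_val, p_raw = np.nan, np.nan
            else:
                t_val, p_raw = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append(
                {
                    "team_a": teams[i],
                    "team_b": teams[j],
                    "mean_diff": float(np.mean(a) - np.mean(b)),
                    "t": float(t_val),
                    "p_raw": float(p_raw),
                    "p_bonf": float(min(1.0, p_raw * m)) if np.isfinite(p_raw) else np.nan,
                }
            )
    n_total = sum(len(s) for s in samples)
    return AnovaResult(
        f=float(f_stat),
        p=float(p_val),
        df_between=len(teams) - 1,
        df_within=n_total - len(teams),
        pairwise=pd.DataFrame(rows),
        degenerate=degenerate,
    )
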