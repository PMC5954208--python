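"""Score a round-robin tournament from a match ledger.

Rebuilds league points from the bundled tournament score tables (3 per
win, 1 per tie), then simulates a small synthetic ledger and derives a full
league table, the win matrix, and a one-way ANOVA on per-game goal
difference with Bonferroni pairwise comparisons.
"""

import numpy as np

from varietywalk import MatchResult, build_league, goal_difference_anova, league_points
from varietywalk.datasets import tournament1_table
from varietywalk.tournament import pairwise_matrices

print("published Tournament-1 records re-scored (points = 3*W + T):")
for team, row in tournament1_table().iterrows():
    wins, ties = int(row["wins"]), int(row["ties"])
    print(f"  {team:12s} W={wins:5d} T={ties:5d} -> "
          f"{league_points(wins, ties):6d} points")

rng = np.random.default_rng(0)
strength = {"alpha": 2.0, "beta": 1.2, "gamma": 0.6}
teams = list(strength)
ledger = [
    MatchResult(a, b, int(rng.poisson(strength[a])), int(rng.poisson(strength[b])))
    for i, a in enumerate(teams)
    for b in teams[i + 1:]
    for _ in range(200)
]

table = build_league(ledger)
print("\nsynthetic 3-team league (200 games per pairing):")
print(table[["league_points", "wins", "losses", "ties", "avg_goal_difference"]])

wins, _ = pairwise_matrices(ledger)
print("\nwin matrix (row beats column):")
print(wins)

res = goal_difference_anova(ledger)
print(f"\none-way ANOVA on per-game goal difference: "
      f"F({res.df_between}, {res.df_within}) = {res.f:.1f}, p = {res.p:.3g}")
print(res.pairwise.to_string(index=False))
print("\nTeams with higher scoring rates collect more points and a larger")
print("average goal difference; the ANOVA confirms the separation.")
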