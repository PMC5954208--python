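"""In-package worked-example fixtures.

Score tables from two simulated RoboCup round-robin tournaments used
throughout the examples and tests: Tournament 1 pits a team trained on
natural free-play walking paths against four geometric/no-training
baselines (5 teams, 1,000 games per pairing, 4,000 games per team);
Tournament 2 pits five teams trained on clustered path groups against a
straight-line baseline (6 teams, 5,000 games per team). Each row carries
the published league points, win/loss/tie record, and mean +/- SE goals
scored and conceded.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["tournament1_table", "tournament2_table", "GAMES_PER_PAIRING"]

#: Every pair of teams met this many times in both tournaments.
GAMES_PER_PAIRING = 1000

_COLS = [
    "team", "league_points", "wins", "losses", "ties",
    "goals_scored_mean", "goals_scored_se",
    "goals_conceded_mean", "goals_conceded_se",
]

_T1 = [
    ("infants",     9701, 2888,   75, 1037, 2.43, 0.04,  0.02, 0.003),
    ("squares",     7463, 1898,  333, 1769, 1.03, 0.02,  0.09, 0.01),
    ("circles",     6602, 1696,  790, 1514, 1.21, 0.03,  0.25, 0.01),
    ("lines",       2927,  611, 2295, 1094, 0.20, 0.01,  1.14, 0.02),
    ("no-training",  400,    0, 3600,  400, 0.00, 0.00,  3.36, 0.03),
]

_T2 = [
    ("purple", 11786, 3420,   54, 1526, 1.46, 0.02,  0.02, 0.001),
    ("red",     9307, 2407,  507, 2086, 0.89, 0.02,  0.13, 0.01),
    ("blue",    8052, 1982,  912, 2106, 0.74, 0.01,  0.23, 0.01),
    ("yellow",  7561, 1795, 1029, 2176, 0.63, 0.01,  0.26, 0.01),
    ("green",   3655,  912, 3169,  919, 0.30, 0.01,  1.15, 0.02),
    ("lines",    155,    0, 4845,  155, 0.00, 0.00,  2.26, 0.01),
]


def tournament1_table() -> pd.DataFrame:
    """Tournament 1 score table (5 teams, 4 opponents x 1,000 games each)."""
    return pd.DataFrame(_T1, columns=_COLS).set_index("team")


def tournament2_table() -> pd.DataFrame:
    """Tournament 2 score table (6 teams, 5 opponents x 1,000 games each)."""
    return pd.DataFrame(_T2, columns=_COLS).set_index("team")
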