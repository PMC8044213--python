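"""Pattern-vector classification of DDMR methylation trajectories.

Each DDMR carries a 3-vector of mean methylation across (proB, wild-type
mature, knockout mature).  The vector is classified against a catalog of
12 template pattern vectors whose components take the discrete levels
low = 0.2, intermediate = 0.5, high = 0.8, by maximum Pearson
correlation coefficient (PCC).  No region is assigned to more than one
pattern; a constant observed vector has no defined correlation and lands
in the unassigned bin.

With only 3 points, Pearson correlation is invariant to affine
transformations of the template, so several {0.2, 0.5, 0.8} templates
are mutually indistinguishable by PCC alone.  There are exactly 12 such
equivalence classes among the 24 non-constant templates, and the default
catalog picks one representative per class; ties at identical PCC are
broken by smallest Euclidean distance to the observed vector (preserving
the low/intermediate/high magnitude semantics), then by catalog order.

The default catalog is a reconstruction: it realizes the trajectory
shapes the study names (developmental demethylation, developmental gain
lost or kept in the knockout, partial demethylation completed by
knockout, paradoxical knockout gain) with one template per PCC class.
A custom catalog can be supplied as a TSV (id + three levels per row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEVELS = (0.2, 0.5, 0.8)  # low, intermediate, high


@dataclass(frozen=True)
class PatternVector:
    """A 3-condition methylation template (proB, WT mature, KO mature)."""

    id: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("pattern vectors are 3-vectors")
        if len(set(self.levels)) == 1:
            raise ValueError("constant pattern vector has undefined correlation")


@dataclass
class PatternAssignment:
    """Max-PCC classification of one region's methylation vector."""

    pattern_id: str
    pcc: float
    runner_up_pcc: float | None


_DEFAULT = [
    # (2,-1,-1)-type shapes (one condition stands apart)
    ("P1", (0.8, 0.2, 0.2)),   # developmental demethylation, stays low in KO
    ("P4", (0.2, 0.8, 0.2)),   # developmental gain, lost in KO
    ("P5", (0.2, 0.8, 0.8)),   # developmental gain, insensitive to KO
    ("P6", (0.8, 0.8, 0.2)),   # stably methylated, erased only in KO
    ("P8", (0.8, 0.2, 0.8)),   # developmental loss, paradoxically restored in KO
    ("P10", (0.2, 0.2, 0.8)),  # stably low, paradoxical gain in KO
    # (1,0,-1)-type shapes (monotone / graded trajectories)
    ("P7", (0.8, 0.5, 0.2)),   # partial demethylation completed by KO
    ("P9", (0.5, 0.8, 0.2)),   # graded developmental gain, lost in KO
    ("P2", (0.8, 0.2, 0.5)),   # developmental loss, partial KO rebound
    ("P3", (0.2, 0.8, 0.5)),   # developmental gain, partial KO loss
    ("P11", (0.5, 0.2, 0.8)),  # loss then paradoxical KO gain
    ("P12", (0.2, 0.5, 0.8)),  # graded gain peaking in KO
]


def default_pattern_catalog() -> list[PatternVector]:
    """The default 12-vector catalog over levels {0.2, 0.5, 0.8}.

    One representative per Pearson-equivalence class of non-constant
    templates, ordered by id; every non-constant {0.2, 0.5, 0.8} vector
    correlates perfectly with exactly one catalog entry.
    """
    cat = [PatternVector(pid, lv) for pid, lv in _DEFAULT]
    return sorted(cat, key=lambda p: int(p.id[1:]))


def read_pattern_catalog(path) -> list[PatternVector]:
    """Load a catalog TSV: columns id, level_proB, level_WT, level_KO."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 4:
        raise ValueError("catalog needs 4 columns: id + three levels")
    return [
        PatternVector(str(r.iloc[0]), (float(r.iloc[1]), float(r.iloc[2]), float(r.iloc[3])))
        for _, r in df.iterrows()
    ]


def write_pattern_catalog(catalog: list[PatternVector], path) -> None:
    pd.DataFrame(
        [(p.id, *p.levels) for p in catalog],
        columns=["id", "level_proB", "level_WT", "level_KO"],
    ).to_csv(path, sep="\t", index=False)


def _pcc3(v: np.ndarray, t: np.ndarray) -> float:
    vc = v - v.mean()
    tc = t - t.mean()
    denom = np.sqrt((vc**2).sum() * (tc**2).sum())
    if denom == 0:
        return np.nan
    return float(np.dot(vc, tc) / denom)


def assign_pattern(
    v, catalog: list[PatternVector] | None = None
) -> PatternAssignment | None:
    """Assign a 3-condition methylation vector to its max-PCC template.

    Returns ``None`` (unassigned) for constant vectors, whose Pearson
    correlation is undefined.  PCC ties — unavoidable for affinely
    equivalent templates — are broken by smallest Euclidean distance to
    the observed vector, then by catalog order.
    """
    catalog = catalog if catalog is not None else default_pattern_catalog()
    v = np.asarray(v, float)
    if v.shape != (3,):
        if len(catalog) and len(catalog[0].levels) != v.size:
            raise ValueError("vector length does not match catalog vectors")
        raise ValueError("expected a 3-vector")
    if np.ptp(v) == 0:
        return None
    pccs = np.array([_pcc3(v, np.asarray(t.levels)) for t in catalog])
    dists = np.array([np.linalg.norm(v - np.asarray(t.levels)) for t in catalog])
    best_pcc = np.nanmax(pccs)
    tied = np.flatnonzero(np.isclose(pccs, best_pcc, atol=1e-12))
    winner = tied[np.argmin(dists[tied])]  # argmin keeps first on distance ties
    others = np.delete(pccs, winner)
    runner_up = float(np.nanmax(others)) if len(others) else None
    return PatternAssignment(
        pattern_id=catalog[winner].id, pcc=float(pccs[winner]), runner_up_pcc=runner_up
    )


def assign_patterns(
    ddmrs: pd.DataFrame,
    catalog: list[PatternVector] | None = None,
    mean_columns: tuple[str, str, str] = ("mean_proB", "mean_WT", "mean_KO"),
) -> pd.DataFrame:
    """Classify every DDMR row; unassigned rows get pattern_id 'unassigned'."""
    catalog = catalog if catalog is not None else default_pattern_catalog()
    ids, pccs = [], []
    for _, rec in ddmrs.iterrows():
        v = rec[list(mean_columns)].to_numpy(float)
        if np.isnan(v).any():
            ids.append("unassigned")
            pccs.append(np.nan)
            continue
        a = assign_pattern(v, catalog)
        ids.append(a.pattern_id if a else "unassigned")
        pccs.append(a.pcc if a else np.nan)
    out = ddmrs.copy()
    out["pattern_id"] = ids
    out["pcc"] = pccs
    return out


def summarize_patterns(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per pattern id over the assigned regions.

    Fractions are taken over assigned regions only and sum to 1; the
    unassigned bin is reported separately with fraction NaN.
    """
    if not len(assignments):
        return pd.DataFrame(columns=["pattern_id", "count", "fraction"])
    counts = assignments["pattern_id"].value_counts()
    assigned = counts.drop("unassigned", errors="ignore")
    total = int(assigned.sum())
    rows = [
        (pid, int(c), c / total if total else np.nan) for pid, c in assigned.items()
    ]
    if "unassigned" in counts.index:
        rows.append(("unassigned", int(counts["unassigned"]), np.nan))
    out = pd.DataFrame(rows, columns=["pattern_id", "count", "fraction"])
    return out.sort_values("pattern_id").reset_index(drop=True)
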