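"""Ligand-receptor communication scoring between annotated groups with a
saturating mass-action probability and a permutation null, aggregated to
pathway strengths and per-group outgoing/incoming totals."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class LRPair:
    pathway: str
    ligand: tuple          # subunit gene names
    receptor: tuple

    @property
    def name(self) -> str:
        return f"{'+'.join(self.ligand)}->{'+'.join(self.receptor)}"


@dataclass
class LRDatabase:
    pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            if not p.ligand or not p.receptor:
                raise ValueError(f"pair {p.name} has an empty subunit list")
            key = (p.pathway, p.name)
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LRDatabase":
        pairs = [
            LRPair(
                pathway=str(row.pathway),
                ligand=tuple(s.strip() for s in str(row.ligand).split(",")),
                receptor=tuple(s.strip() for s in str(row.receptor).split(",")),
            )
            for row in df.itertuples()
        ]
        return cls(pairs=pairs)


def default_lr_database() -> LRDatabase:
    """The MK and SPP1 pathway pairs used in the niche analysis."""
    mk = [("MDK", r) for r in [("NCL",), ("SDC1",), ("SDC2",), ("PTPRZ1",),
                               ("ITGA6", "ITGB1")]]
    spp1 = [("SPP1", r) for r in [("CD44",), ("ITGAV", "ITGB1")]]
    pairs = [LRPair("MK", (l,), r) for l, r in mk]
    pairs += [LRPair("SPP1", (l,), r) for l, r in spp1]
    return LRDatabase(pairs=pairs)


@dataclass
class CommResult:
    probabilities: pd.DataFrame   # columns sender, receiver, pathway, pair, prob
    p_values: np.ndarray
    groups: list

    def table(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out["p"] = self.p_values
        return out


def group_mean(
    matrix: ExpressionMatrix,
    labels,
    trim: float = 0.1,
) -> pd.DataFrame:
    """Trimmed mean of normalized expression per gene per group; groups with
    fewer than 3 cells are excluded with a warning."""
    labels = np.asarray(labels, dtype=object)
    expr = matrix.normalized(log=False)
    cols = {}
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() < 3:
            warnings.warn(f"group {g!r} has fewer than 3 cells; excluded")
            continue
        sub = expr[:, mask]
        cols[g] = sub.mean(axis=1) if trim == 0 else stats.trim_mean(sub, trim, axis=1)
    if not cols:
        raise ValueError("no group with at least 3 cells")
    return pd.DataFrame(cols, index=matrix.genes)


def lr_probability(ligand: float, receptor: float, kh: float = 0.5) -> float:
    """Saturating interaction probability P = LR / (kh + LR)."""
    if ligand < 0 or receptor < 0:
        raise ValueError("expression values must be non-negative")
    lr = ligand * receptor
    return lr / (kh + lr)


def _complex_value(means: pd.Series, subunits: tuple) -> float:
    """Geometric mean over subunits; a missing or zero subunit zeroes the
    complex (all subunits are required)."""
    vals = np.asarray([float(means.get(s, 0.0)) for s in subunits])
    if np.any(vals <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def _probability_table(gmeans: pd.DataFrame, db: LRDatabase, kh: float) -> pd.DataFrame:
    rows = []
    for sender in gmeans.columns:
        for receiver in gmeans.columns:
            for pair in db.pairs:
                lig = _complex_value(gmeans[sender], pair.ligand)
                rec = _complex_value(gmeans[receiver], pair.receptor)
                rows.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "pathway": pair.pathway,
                        "pair": pair.name,
                        "prob": lr_probability(lig, rec, kh),
                    }
                )
    return pd.DataFrame(rows)


def permutation_test(
    matrix: ExpressionMatrix,
    labels,
    db: LRDatabase,
    n_perm: int = 100,
    kh: float = 0.5,
    trim: float = 0.1,
    seed: int = 0,
) -> CommResult:
    """Observed sender/receiver/pair probabilities with label-permutation
    p-values: p = (1 + #{permuted >= observed}) / (1 + n_perm)."""
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    labels = np.asarray(labels, dtype=object)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)

    gmeans = group_mean(matrix, labels, trim=trim)
    obs = _probability_table(gmeans, db, kh)
    exceed = np.zeros(len(obs))
    for _ in range(n_perm):
        perm = labels.copy()
        rng.shuffle(perm)
        pm = group_mean(matrix, perm, trim=trim)
        pt = _probability_table(pm, db, kh)
        exceed += pt["prob"].to_numpy() >= obs["prob"].to_numpy()
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return CommResult(probabilities=obs, p_values=pvals, groups=list(gmeans.columns))


def aggregate(comm: CommResult, alpha: float = 0.05) -> dict:
    """Zero out pairs with p >= alpha, then sum probabilities per pathway
    and per-group outgoing/incoming totals."""
    tab = comm.table()
    tab["sig_prob"] = np.where(tab["p"] < alpha, tab["prob"], 0.0)
    pathway = (
        tab.groupby("pathway")["sig_prob"].sum().sort_values(ascending=False)
    )
    outgoing = tab.groupby("sender")["sig_prob"].sum()
    incoming = tab.groupby("receiver")["sig_prob"].sum()
    return {
        "pathway_strength": pathway,
        "outgoing": outgoing.reindex(comm.groups, fill_value=0.0),
        "incoming": incoming.reindex(comm.groups, fill_value=0.0),
    }
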