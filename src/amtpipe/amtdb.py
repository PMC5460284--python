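"""Master accurate-mass-and-time (AMT) tag database: build and match.

An AMT entry is one peptide's reference record — the average mass and
median NET over all of its score-filtered MS/MS observations.  UMCs that
eluted without an MS/MS identification are assigned a peptide ID by
matching against the database inside a joint mass (ppm) and NET
tolerance window; among multiple candidates the smallest normalized
distance d = (dppm/mass_tol)^2 + (dNET/net_tol)^2 wins, and an exact tie
is left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .umc import ppm_diff

ASSIGN_MSMS = "MSMS"
ASSIGN_AMT = "AMT"


@dataclass
class MatchParams:
    mass_tol_ppm: float = 10.0
    net_tol: float = 0.02
    score_threshold: float = 3.0

    def validate(self) -> None:
        if self.mass_tol_ppm <= 0 or self.net_tol <= 0 or self.score_threshold <= 0:
            raise ConfigurationError("all match parameters must be strictly positive")


def build_amt_db(identified_umcs: pd.DataFrame, params: MatchParams | None = None) -> pd.DataFrame:
    """Compile score-filtered identified UMCs into the master AMT DB.

    One entry per distinct peptide sequence: average observation mass,
    median observation NET, best score, observation count, union of
    protein accessions.  Observations below the score threshold are
    dropped before aggregation; an empty result is a valid empty DB.
    """
    params = params or MatchParams()
    params.validate()
    required = {"peptide_seq", "umc_mass_da", "net", "id_score"}
    if not identified_umcs.empty and not required <= set(identified_umcs.columns):
        raise InputError(f"identified UMCs need columns {sorted(required)}")
    if identified_umcs.empty:
        return pd.DataFrame(columns=["peptide_seq", "avg_mass_da", "median_net",
                                     "best_score", "n_obs", "protein_ids"])
    obs = identified_umcs[identified_umcs["peptide_seq"].notna()]
    obs = obs[obs["id_score"] >= params.score_threshold]
    rows = []
    for seq, grp in obs.groupby("peptide_seq", sort=True):
        acc: list[str] = []
        if "protein_ids" in grp.columns:
            for p in grp["protein_ids"]:
                for a in p:
                    if a not in acc:
                        acc.append(a)
        rows.append(
            (
                seq,
                float(grp["umc_mass_da"].mean()),
                float(grp["net"].median()),
                float(grp["id_score"].max()),
                int(len(grp)),
                tuple(acc),
            )
        )
    db = pd.DataFrame(rows, columns=["peptide_seq", "avg_mass_da", "median_net",
                                     "best_score", "n_obs", "protein_ids"])
    return db.sort_values("avg_mass_da", kind="mergesort").reset_index(drop=True)


class _IndexedDB:
    """Mass-sorted view of the AMT DB for windowed candidate lookup.

    ``positions`` maps each sorted row back to the caller's positional
    row, so match results always refer to the input table's order.
    """

    def __init__(self, db: pd.DataFrame):
        order = np.argsort(db["avg_mass_da"].to_numpy(), kind="stable")
        self.source = db.reset_index(drop=True)
        self.positions = order
        self.mass = db["avg_mass_da"].to_numpy(dtype=float)[order]
        self.net = db["median_net"].to_numpy(dtype=float)[order]


def match_umc_to_amt(
    umc_mass_da: float,
    net: float,
    db: pd.DataFrame | _IndexedDB,
    params: MatchParams | None = None,
):
    """Match one unidentified UMC against the AMT DB.

    Returns ``(row_index_into_db, status, n_candidates, distance)`` where
    status is ``"assigned"``, ``"none"`` or ``"ambiguous"``; the row index
    is None unless assigned.
    """
    params = params or MatchParams()
    params.validate()
    idx = db if isinstance(db, _IndexedDB) else _IndexedDB(db)
    if len(idx.mass) == 0:
        raise InputError("AMT DB is empty")
    t = params.mass_tol_ppm * 1e-6
    lo = np.searchsorted(idx.mass, umc_mass_da / (1.0 + t), side="left")
    hi = np.searchsorted(idx.mass, umc_mass_da * (1.0 + t), side="right")
    if hi <= lo:
        return None, "none", 0, np.nan
    cand = np.arange(lo, hi)
    dppm = ppm_diff(umc_mass_da, idx.mass[cand])
    dnet = np.abs(net - idx.net[cand])
    ok = (dppm <= params.mass_tol_ppm) & (dnet <= params.net_tol)
    cand, dppm, dnet = cand[ok], dppm[ok], dnet[ok]
    n = len(cand)
    if n == 0:
        return None, "none", 0, np.nan
    d = (dppm / params.mass_tol_ppm) ** 2 + (dnet / params.net_tol) ** 2
    best = np.argmin(d)
    if n > 1 and np.sum(d == d[best]) > 1:
        return None, "ambiguous", n, float(d[best])
    return int(idx.positions[cand[best]]), "assigned", n, float(d[best])


def assign_all(
    umcs: pd.DataFrame, db: pd.DataFrame, params: MatchParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign AMT-matched peptide IDs to every unidentified UMC.

    MS/MS-identified UMCs pass through untouched (source ``MSMS``);
    matched UMCs gain the AMT entry's peptide/protein record (source
    ``AMT``).  Within each run one peptide is reported once: the
    highest-intensity UMC is kept, the rest are flagged ``duplicate``.
    Returns ``(annotated UMC table, per-UMC match report)``.
    """
    params = params or MatchParams()
    params.validate()
    out = umcs.copy().reset_index(drop=True)
    out["source"] = None
    out.loc[out["peptide_seq"].notna(), "source"] = ASSIGN_MSMS
    report_rows = []
    if not db.empty:
        idx = _IndexedDB(db)
        unid = out.index[out["peptide_seq"].isna()]
        for i in unid:
            hit, status, n_cand, dist = match_umc_to_amt(
                out.at[i, "umc_mass_da"], out.at[i, "net"], idx, params
            )
            report_rows.append((out.at[i, "umc_id"], status, n_cand, dist))
            if hit is not None:
                out.at[i, "peptide_seq"] = idx.source.at[hit, "peptide_seq"]
                out.at[i, "protein_ids"] = idx.source.at[hit, "protein_ids"]
                out.at[i, "source"] = ASSIGN_AMT
    report = pd.DataFrame(report_rows,
                          columns=["umc_id", "status", "n_candidates", "distance"])
    # one intensity per peptide per run: keep the most intense UMC
    out["duplicate"] = False
    assigned = out[out["peptide_seq"].notna()]
    for (_, _), grp in assigned.groupby(["run_id", "peptide_seq"], sort=False):
        if len(grp) > 1:
            keep = grp["umc_intensity"].idxmax()
            out.loc[grp.index.difference([keep]), "duplicate"] = True
    return out, report
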