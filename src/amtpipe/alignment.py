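"""The peptide x sample alignment table: build, rescue, normalize, compare.

The alignment table collects one UMC intensity per identified/assigned
peptide per run; a missing cell means the peptide was seen in no UMC of
that run.  Missing cells can be rescued from the pool of leftover
unassigned UMCs under a tiered NET tolerance (tighter across technical
replicates than across biological replicates).  Quantile normalization
forces every sample's intensity distribution onto the mean order
statistics, with a quantile-interpolation variant for columns of unequal
observed counts so that missing values stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .errors import ColumnError, InputError
from .umc import ppm_diff

PROV_MSMS = "MSMS"
PROV_AMT = "AMT"
PROV_RESCUE = "RESCUE"


@dataclass
class AlignmentTable:
    """Peptide rows x run columns with per-cell provenance.

    ``intensities`` holds UMC intensities (or their log2 after
    :func:`log2_transform`); ``provenance`` is a same-shaped frame of
    MSMS / AMT / RESCUE / '' strings; ``peptides`` carries the consensus
    mass, consensus NET and protein accessions per row; ``design`` is
    indexed by run_id with group / bio_rep / tech_rep columns.
    """

    intensities: pd.DataFrame
    provenance: pd.DataFrame
    peptides: pd.DataFrame
    design: pd.DataFrame
    log_scale: bool = False

    @property
    def shape(self):
        return self.intensities.shape

    def n_missing(self) -> int:
        return int(self.intensities.isna().sum().sum())


def build_alignment_table(assigned_umcs: pd.DataFrame, design: pd.DataFrame) -> AlignmentTable:
    """Combine per-run assigned UMCs into the n x m alignment table.

    Rows are the union of peptides over runs; each cell takes the run's
    UMC intensity with its assignment provenance.  Duplicate
    (peptide, run) pairs must have been resolved upstream.
    """
    design = design.set_index("run_id") if "run_id" in design.columns else design
    umcs = assigned_umcs[assigned_umcs["peptide_seq"].notna()]
    if "duplicate" in umcs.columns:
        umcs = umcs[~umcs["duplicate"].astype(bool)]
    unknown = set(umcs["run_id"]) - set(design.index)
    if unknown:
        raise InputError(f"runs missing from design: {sorted(unknown)}")
    if umcs.duplicated(["peptide_seq", "run_id"]).any():
        raise InputError("duplicate (peptide, run) pairs; resolve duplicates upstream")

    intensities = umcs.pivot(index="peptide_seq", columns="run_id", values="umc_intensity")
    intensities = intensities.reindex(columns=design.index)
    prov = umcs.pivot(index="peptide_seq", columns="run_id", values="source")
    prov = prov.reindex(index=intensities.index, columns=design.index).fillna("")

    meta_rows = []
    for seq, grp in umcs.groupby("peptide_seq", sort=True):
        w = grp["umc_intensity"].to_numpy(dtype=float)
        mass = float((grp["umc_mass_da"].to_numpy() * w).sum() / w.sum())
        net = float(grp["net"].median())
        acc: list[str] = []
        for p in grp["protein_ids"]:
            for a in p:
                if a not in acc:
                    acc.append(a)
        meta_rows.append((seq, mass, net, tuple(sorted(acc))))
    peptides = pd.DataFrame(
        meta_rows, columns=["peptide_seq", "consensus_mass_da", "consensus_net", "protein_ids"]
    ).set_index("peptide_seq")

    intensities = intensities.sort_index()
    prov = prov.loc[intensities.index]
    peptides = peptides.loc[intensities.index]
    return AlignmentTable(intensities=intensities, provenance=prov,
                          peptides=peptides, design=design)


def rescue_missing(
    table: AlignmentTable,
    umc_pool: pd.DataFrame,
    mass_tol_ppm: float = 10.0,
    tech_net_tol: float = 0.01,
    bio_net_tol: float = 0.02,
) -> AlignmentTable:
    """Fill missing cells from leftover unassigned UMCs.

    For a missing cell (peptide p, run r) the candidate pool is the
    unassigned UMCs of run r within the mass tolerance of p's consensus
    mass and within the NET tolerance — the technical-replicate tolerance
    when another run of the same mouse contains p, the biological one
    otherwise.  Candidates are consumed greedily by ascending normalized
    distance; a UMC fills at most one cell and no filled cell is ever
    overwritten.
    """
    if table.log_scale:
        raise InputError("rescue operates on the linear-intensity table")
    pool = umc_pool[umc_pool["peptide_seq"].isna()] if "peptide_seq" in umc_pool.columns else umc_pool
    by_run = {}
    for run_id, grp in pool.groupby("run_id"):
        order = np.argsort(grp["umc_mass_da"].to_numpy(), kind="stable")
        g = grp.iloc[order]
        by_run[run_id] = (
            g["umc_mass_da"].to_numpy(dtype=float),
            g["net"].to_numpy(dtype=float),
            g["umc_intensity"].to_numpy(dtype=float),
            g.index.to_numpy(),
        )

    bio_of = table.design["bio_rep"].to_dict()
    X = table.intensities
    candidates = []  # (distance, peptide, run, pool_row_label, intensity)
    t = mass_tol_ppm * 1e-6
    for seq, row in X.iterrows():
        present_bios = {bio_of[r] for r in X.columns[row.notna()]}
        cmass = table.peptides.at[seq, "consensus_mass_da"]
        cnet = table.peptides.at[seq, "consensus_net"]
        for run_id in X.columns[row.isna()]:
            if run_id not in by_run:
                continue
            net_tol = tech_net_tol if bio_of[run_id] in present_bios else bio_net_tol
            mass, net, inten, labels = by_run[run_id]
            lo = np.searchsorted(mass, cmass / (1.0 + t), side="left")
            hi = np.searchsorted(mass, cmass * (1.0 + t), side="right")
            if hi <= lo:
                continue
            sel = np.arange(lo, hi)
            dppm = ppm_diff(cmass, mass[sel])
            dnet = np.abs(cnet - net[sel])
            ok = (dppm <= mass_tol_ppm) & (dnet <= net_tol)
            for j, p, n_ in zip(sel[ok], dppm[ok], dnet[ok]):
                d = (p / mass_tol_ppm) ** 2 + (n_ / net_tol) ** 2
                candidates.append((d, seq, run_id, labels[j], inten[j]))

    candidates.sort(key=lambda c: (c[0], c[1], str(c[2])))
    new_int = table.intensities.copy()
    new_prov = table.provenance.copy()
    used_umcs: set = set()
    filled: set[tuple] = set()
    for d, seq, run_id, label, inten in candidates:
        if label in used_umcs or (seq, run_id) in filled:
            continue
        used_umcs.add(label)
        filled.add((seq, run_id))
        new_int.at[seq, run_id] = inten
        new_prov.at[seq, run_id] = PROV_RESCUE
    return replace(table, intensities=new_int, provenance=new_prov)


def log2_transform(table: AlignmentTable) -> AlignmentTable:
    if table.log_scale:
        return table
    return replace(table, intensities=np.log2(table.intensities), log_scale=True)


def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Missing-aware quantile normalization of a sample-column frame.

    With complete data every column's sorted values become the
    across-column mean order statistics.  With missing values each
    observed value is mapped through its within-column quantile fraction
    onto the interpolated reference curve; missing cells stay missing.
    """
    if values.shape[1] < 2:
        return values.copy()
    n_obs = values.notna().sum(axis=0)
    for col, n in n_obs.items():
        if n < 2:
            raise ColumnError(f"column {col!r} has {n} observed values; cannot normalize")
    k = int(n_obs.max())
    grid = np.linspace(0.0, 1.0, k)
    curves = np.empty((values.shape[1], k))
    for j, col in enumerate(values.columns):
        v = np.sort(values[col].dropna().to_numpy(dtype=float))
        curves[j] = np.interp(grid, np.linspace(0.0, 1.0, len(v)), v)
    reference = curves.mean(axis=0)

    out = values.copy()
    for col in values.columns:
        obs = values[col].dropna()
        ranks = rankdata(obs.to_numpy(dtype=float), method="average")
        frac = (ranks - 1.0) / (len(obs) - 1.0)
        out.loc[obs.index, col] = np.interp(frac, grid, reference)
    return out


def quantile_normalize(table: AlignmentTable) -> AlignmentTable:
    return replace(table, intensities=quantile_normalize_frame(table.intensities))


def dataset_similarity(table: AlignmentTable, run_a: str, run_b: str):
    """Reproducibility scores between two runs.

    Returns ``(jaccard, pearson)``: the Jaccard index of the detected
    peptide sets and the Pearson correlation of log2 intensities over
    shared peptides (None when fewer than 3 peptides are shared).
    """
    a = table.intensities[run_a]
    b = table.intensities[run_b]
    set_a, set_b = set(a.dropna().index), set(b.dropna().index)
    union = set_a | set_b
    jaccard = len(set_a & set_b) / len(union) if union else 0.0
    shared = sorted(set_a & set_b)
    if len(shared) < 3:
        return jaccard, None
    va, vb = a.loc[shared].to_numpy(dtype=float), b.loc[shared].to_numpy(dtype=float)
    if not table.log_scale:
        va, vb = np.log2(va), np.log2(vb)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return jaccard, None
    return jaccard, float(pearsonr(va, vb).statistic)
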