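"""Unique-mass-class (UMC) formation from per-run deisotoped ion features.

A UMC groups the MS features of one eluting peptide species within one
LC-MS run.  Grouping is single linkage in neutral monoisotopic mass
(charge states pool together because features arrive as neutral masses)
followed by a split wherever consecutive member scans gap by more than
``max_scan_gap``.  The UMC mass is the intensity-weighted mean of member
masses, the UMC intensity their sum, and the elution representative the
median member scan, normalized onto [0, 1] per run (NET).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateRunError, InputError

UMC_FIELDS = [
    "umc_id", "run_id", "umc_mass_da", "umc_intensity", "n_ions",
    "scan_min", "scan_median", "scan_max",
]


def ppm_diff(m1, m2):
    """Relative mass difference in ppm: 1e6 * |m1 - m2| / min(m1, m2)."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    return 1e6 * np.abs(m1 - m2) / np.minimum(m1, m2)


def umc_mass(masses: Sequence[float], intensities: Sequence[float]) -> float:
    """Intensity-weighted average of member monoisotopic masses."""
    masses = np.asarray(masses, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if masses.size == 0:
        raise InputError("a UMC needs at least one member ion")
    total = intensities.sum()
    if total <= 0:
        raise InputError("total member intensity must be positive")
    return float((masses * intensities).sum() / total)


def umc_intensity(intensities: Sequence[float]) -> float:
    """Summed abundance of all member ions."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        raise InputError("a UMC needs at least one member ion")
    return float(intensities.sum())


def group_ions_to_umcs(
    features: pd.DataFrame, mass_tol_ppm: float = 10.0, max_scan_gap: int = 5
) -> pd.DataFrame:
    """Partition one run's ion features into UMCs.

    Returns one row per UMC with mass/intensity/scan summaries and a
    ``member_rows`` column holding the input index labels of the member
    ions (the partition is exact: every ion lands in exactly one UMC).
    """
    if features.empty:
        out = pd.DataFrame(columns=UMC_FIELDS + ["member_rows"])
        return out
    if features["run_id"].nunique() > 1:
        raise InputError("group_ions_to_umcs expects features from a single run")
    run_id = features["run_id"].iloc[0]

    masses = features["monoiso_mass_da"].to_numpy(dtype=float)
    scans = features["scan"].to_numpy(dtype=float)
    intens = features["intensity"].to_numpy(dtype=float)
    if (masses <= 0).any() or (intens <= 0).any():
        raise InputError("masses and intensities must be strictly positive")

    order = np.argsort(masses, kind="stable")
    m_sorted = masses[order]
    # single-linkage mass chains: break where adjacent sorted masses differ
    # by more than the tolerance (transitive closure of the pairwise link)
    gap = ppm_diff(m_sorted[:-1], m_sorted[1:]) > mass_tol_ppm
    chain = np.concatenate([[0], np.cumsum(gap)])
    labels = np.empty(len(features), dtype=int)
    next_label = 0
    for c in range(chain[-1] + 1):
        members = order[chain == c]
        # split the chain on elution gaps
        s_order = members[np.argsort(scans[members], kind="stable")]
        s = scans[s_order]
        splits = np.concatenate([[0], np.cumsum(np.diff(s) > max_scan_gap)])
        for k in range(splits[-1] + 1):
            labels[s_order[splits == k]] = next_label
            next_label += 1

    rows = []
    index = features.index.to_numpy()
    for lab in range(next_label):
        sel = labels == lab
        rows.append(
            (
                f"{run_id}:U{lab:06d}",
                run_id,
                umc_mass(masses[sel], intens[sel]),
                umc_intensity(intens[sel]),
                int(sel.sum()),
                int(scans[sel].min()),
                float(np.median(scans[sel])),
                int(scans[sel].max()),
                list(index[sel]),
            )
        )
    out = pd.DataFrame(rows, columns=UMC_FIELDS + ["member_rows"])
    return out.sort_values("umc_mass_da", kind="mergesort").reset_index(drop=True)


def attach_ids(umcs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Inherit MS/MS peptide IDs from identified member ions.

    A UMC whose identified members agree on one peptide sequence carries
    that ID (best score, union of protein accessions); members identified
    as different peptides leave the UMC unidentified with a conflict flag.
    A ``true_peptide`` column, if present in the features, is propagated
    (majority by intensity) for simulation scoring only.
    """
    umcs = umcs.copy()
    seqs, scores, prots, conflicts, truths = [], [], [], [], []
    has_truth = "true_peptide" in features.columns
    for members in umcs["member_rows"]:
        sub = features.loc[members]
        ided = sub[sub["peptide_seq"].notna()]
        unique = ided["peptide_seq"].unique()
        if len(unique) == 1:
            seqs.append(unique[0])
            scores.append(float(ided["id_score"].max()))
            acc: list[str] = []
            for p in ided["protein_ids"]:
                for a in p:
                    if a not in acc:
                        acc.append(a)
            prots.append(tuple(acc))
            conflicts.append(False)
        else:
            seqs.append(None)
            scores.append(np.nan)
            prots.append(())
            conflicts.append(len(unique) > 1)
        if has_truth:
            top = sub["intensity"].idxmax()
            truths.append(sub.loc[top, "true_peptide"])
    umcs["peptide_seq"] = seqs
    umcs["id_score"] = scores
    umcs["protein_ids"] = prots
    umcs["id_conflict"] = conflicts
    if has_truth:
        umcs["true_peptide"] = truths
    return umcs


def compute_net(
    umcs: pd.DataFrame, calibration: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Normalized elution time per UMC for one run.

    Raw NET min-max scales the median member scan onto the run's observed
    scan range.  With a calibration map (peptide -> reference NET), a
    least-squares line from raw NET to the reference is fitted on the
    run's identified UMCs and applied to all UMCs (clipped to [0, 1]);
    this is the cross-run elution alignment step.
    """
    if umcs.empty:
        out = umcs.copy()
        out["net"] = pd.Series(dtype=float)
        return out
    if umcs["run_id"].nunique() > 1:
        raise InputError("compute_net expects UMCs from a single run")
    lo = float(umcs["scan_min"].min())
    hi = float(umcs["scan_max"].max())
    if hi == lo:
        raise DegenerateRunError("run has a single distinct scan; NET undefined")
    out = umcs.copy()
    raw = (out["scan_median"].to_numpy(dtype=float) - lo) / (hi - lo)
    if calibration is not None:
        if "peptide_seq" not in out.columns:
            raise InputError("calibration requires identified UMCs (run attach_ids first)")
        mask = out["peptide_seq"].notna() & out["peptide_seq"].isin(calibration)
        if mask.sum() < 2:
            raise InputError("need >= 2 identified UMCs with reference NETs to calibrate")
        x = raw[mask.to_numpy()]
        y = np.array([calibration[s] for s in out.loc[mask, "peptide_seq"]])
        if np.ptp(x) == 0:
            raise DegenerateRunError("calibration points share one raw NET")
        slope, intercept = np.polyfit(x, y, 1)
        raw = np.clip(slope * raw + intercept, 0.0, 1.0)
    out["net"] = raw
    return out


def quantify_run(
    features: pd.DataFrame,
    mass_tol_ppm: float = 10.0,
    max_scan_gap: int = 5,
    calibration: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Full per-run quantification: group, attach IDs, compute NET."""
    umcs = group_ions_to_umcs(features, mass_tol_ppm=mass_tol_ppm,
                              max_scan_gap=max_scan_gap)
    if umcs.empty:
        for col in ("peptide_seq", "id_score", "protein_ids", "id_conflict", "net"):
            umcs[col] = pd.Series(dtype=object)
        return umcs
    umcs = attach_ids(umcs, features)
    return compute_net(umcs, calibration=calibration)
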