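"""Ground-truthed synthetic data for the label-free LC-MS / mRNA pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, with every latent quantity recorded so that recovery can be
scored exactly:

* a peptide universe: tryptic-like sequences with monoisotopic masses
  (computed from the sequence composition) and latent normalized elution
  times (NET) on [0, 1];
* per-run deisotoped ion-feature tables: each detected peptide emits a
  short train of co-eluting ions with ppm-scale mass error, NET drift
  mapped onto an integer scan axis, and log-normal intensity noise; a
  Bernoulli subset of peptide detections carries an MS/MS identification
  with a search score;
* protein-level group effects (log2 units) propagated to all of the
  protein's peptides, and a wild-type vs conditional-knockout expression
  matrix with the same planted effects plus extra genes never seen at
  the protein level.

Randomness is organized as one independent stream per concern (universe,
truth, expression, each run), all derived from the master seed, so adding
runs or stages never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import os
import zlib
from typing import Mapping

import numpy as np
import pandas as pd
from pyteomics import mass as pt_mass

from . import io
from .errors import ConfigurationError

GROUP_CONTROL = "WT"
GROUP_CASE = "CKO"

# residue alphabet for simulated tryptic peptides (C-terminal K/R)
_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))
_MASS_RANGE = (600.0, 4000.0)

# sub-stream indices off the master seed; run/sample streams are keyed by
# a CRC of the run id so adding runs never perturbs existing draws
_STREAM_UNIVERSE = 1
_STREAM_TRUTH = 2
_STREAM_EXPRESSION = 3
_STREAM_ANNOTATION = 4
_STREAM_RUN = 5
_STREAM_OBS = 6
_STREAM_SAMPLE = 7


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; a fixed seed fixes every draw."""

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (5, 10)
    n_bio_per_group: int = 3
    n_tech_per_bio: int = 1
    n_scans: int = 1000
    mass_error_ppm_sd: float = 2.0
    net_error_sd: float = 0.005
    log2_intensity_mean: float = 20.0
    log2_intensity_sd: float = 2.0
    intensity_noise_sd: float = 0.25
    detection_rate: float = 0.9
    id_rate: float = 0.6
    low_score_rate: float = 0.1
    shared_peptide_rate: float = 0.05
    de_fraction: float = 0.1
    effect_size: float = 1.0
    n_extra_genes: int = 800
    expr_baseline_log2_mean: float = 8.0
    expr_baseline_log2_sd: float = 2.0
    expr_noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigurationError("peptides_per_protein range must satisfy 1 <= lo <= hi")
        if self.n_bio_per_group < 2:
            raise ConfigurationError("need >= 2 biological samples per group")
        if self.n_tech_per_bio < 1:
            raise ConfigurationError("n_tech_per_bio must be >= 1")
        if self.n_scans < 2:
            raise ConfigurationError("n_scans must be >= 2")
        for name in ("detection_rate", "id_rate", "low_score_rate",
                     "shared_peptide_rate", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("mass_error_ppm_sd", "net_error_sd", "log2_intensity_sd",
                     "intensity_noise_sd", "expr_baseline_log2_sd", "expr_noise_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_extra_genes < 0:
            raise ConfigurationError("n_extra_genes must be >= 0")
        if self.seed is None:
            raise ConfigurationError("seed is required")


@dataclass
class PeptideUniverse:
    """Latent peptide catalog: sequence, true mass/NET, protein membership."""

    peptides: pd.DataFrame  # peptide_seq, protein_ids, proteotypic, true_mass_da, true_net

    @property
    def proteins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for seq, prots in zip(self.peptides["peptide_seq"], self.peptides["protein_ids"]):
            for p in prots:
                out.setdefault(p, []).append(seq)
        return out

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class TruthTable:
    """Planted effects and per-run detection flags; the scoring key."""

    proteins: pd.DataFrame      # protein_id, gene_id, direction, effect_log2
    genes: pd.DataFrame         # gene_id, protein_id, direction, effect_log2
    peptides: pd.DataFrame      # peptide_seq, baseline_log2, effect_log2
    observations: pd.DataFrame  # peptide_seq, run_id, true_log2, observed
    config: SimulationConfig = field(repr=False, default=None)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _rng_keyed(seed: int, stream: int, key: str) -> np.random.Generator:
    crc = zlib.crc32(key.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), crc]))


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> tuple[str, float]:
    """One unique tryptic-like sequence whose monoisotopic mass is in range."""
    while True:
        length = int(rng.integers(6, 31))
        body = "".join(rng.choice(_RESIDUES, size=length - 1))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        m = pt_mass.fast_mass(seq)
        if _MASS_RANGE[0] <= m <= _MASS_RANGE[1] and seq not in taken:
            taken.add(seq)
            return seq, m


def generate_universe(config: SimulationConfig) -> PeptideUniverse:
    """Draw the latent peptide catalog.

    Masses come from the simulated sequences themselves (so near-isobaric
    peptides occur at a realistic rate); NETs are uniform on [0, 1].  A
    configurable fraction of peptides is shared with a second protein and
    therefore flagged non-proteotypic.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_UNIVERSE)
    lo, hi = config.peptides_per_protein
    protein_ids = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    taken: set[str] = set()
    rows = []
    for pid in protein_ids:
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            seq, m = _random_peptide(rng, taken)
            rows.append((seq, [pid], m, float(rng.uniform())))
    # shared (non-proteotypic) peptides
    if config.n_proteins > 1 and config.shared_peptide_rate > 0:
        share = rng.random(len(rows)) < config.shared_peptide_rate
        for i in np.flatnonzero(share):
            seq, prots, m, net = rows[i]
            other = protein_ids[int(rng.integers(config.n_proteins))]
            if other not in prots:
                prots.append(other)
    df = pd.DataFrame(
        {
            "peptide_seq": [r[0] for r in rows],
            "protein_ids": [tuple(r[1]) for r in rows],
            "true_mass_da": [r[2] for r in rows],
            "true_net": [r[3] for r in rows],
        }
    )
    df["proteotypic"] = df["protein_ids"].map(len) == 1
    return PeptideUniverse(peptides=df)


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Run-level design: groups x biological x technical replicates."""
    rows = []
    for group in (GROUP_CONTROL, GROUP_CASE):
        for b in range(1, config.n_bio_per_group + 1):
            bio = f"{group}_b{b}"
            for t in range(1, config.n_tech_per_bio + 1):
                rows.append((f"{bio}_t{t}", group, bio, t))
    return pd.DataFrame(rows, columns=["run_id", "group", "bio_rep", "tech_rep"])


def expression_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample-level design for the expression matrix (one column per mouse)."""
    design = make_design(config)
    out = design[["bio_rep", "group"]].drop_duplicates().reset_index(drop=True)
    return out.rename(columns={"bio_rep": "sample"})


def _assign_directions(rng, ids, de_fraction, effect_size):
    n = len(ids)
    n_de = int(round(de_fraction * n))
    n_up = (n_de + 1) // 2
    order = rng.permutation(n)
    direction = np.full(n, "null", dtype=object)
    effect = np.zeros(n)
    direction[order[:n_up]] = "up"
    effect[order[:n_up]] = effect_size
    direction[order[n_up:n_de]] = "down"
    effect[order[n_up:n_de]] = -effect_size
    return direction, effect


def plant_truth(universe: PeptideUniverse, config: SimulationConfig) -> TruthTable:
    """Assign group effects to proteins/genes and detection flags per run.

    Protein effects propagate to every peptide of the protein (the first
    accession is the effect donor for shared peptides).  Mapped genes carry
    the same planted effect as their protein; extra genes (expressed but
    never detected as protein) receive independent draws at the same DE
    fraction.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TRUTH)
    protein_ids = sorted({p for prots in universe.peptides["protein_ids"] for p in prots})
    direction, effect = _assign_directions(rng, protein_ids, config.de_fraction,
                                           config.effect_size)
    proteins = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_id": [p.replace("P", "G", 1) for p in protein_ids],
            "direction": direction,
            "effect_log2": effect,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": proteins["gene_id"],
            "protein_id": proteins["protein_id"],
            "direction": proteins["direction"],
            "effect_log2": proteins["effect_log2"],
        }
    )
    if config.n_extra_genes:
        extra_ids = [f"GX{i:05d}" for i in range(1, config.n_extra_genes + 1)]
        d, e = _assign_directions(rng, extra_ids, config.de_fraction, config.effect_size)
        extra = pd.DataFrame(
            {"gene_id": extra_ids, "protein_id": None, "direction": d, "effect_log2": e}
        )
        genes = pd.concat([genes, extra], ignore_index=True)

    eff_by_protein = dict(zip(proteins["protein_id"], proteins["effect_log2"]))
    pep = universe.peptides
    peptides = pd.DataFrame(
        {
            "peptide_seq": pep["peptide_seq"],
            "baseline_log2": rng.normal(config.log2_intensity_mean,
                                        config.log2_intensity_sd, len(pep)),
            "effect_log2": [eff_by_protein[prots[0]] for prots in pep["protein_ids"]],
        }
    )

    design = make_design(config)
    group_by_run = dict(zip(design["run_id"], design["group"]))
    obs_frames = []
    for run_id in design["run_id"]:
        rng_obs = _rng_keyed(config.seed, _STREAM_OBS, run_id)
        observed = rng_obs.random(len(peptides)) < config.detection_rate
        shift = peptides["effect_log2"].to_numpy() if group_by_run[run_id] == GROUP_CASE else 0.0
        obs_frames.append(
            pd.DataFrame(
                {
                    "peptide_seq": peptides["peptide_seq"],
                    "run_id": run_id,
                    "true_log2": peptides["baseline_log2"].to_numpy() + shift,
                    "observed": observed,
                }
            )
        )
    observations = pd.concat(obs_frames, ignore_index=True)
    return TruthTable(proteins=proteins, genes=genes, peptides=peptides,
                      observations=observations, config=config)


def simulate_runs(
    universe: PeptideUniverse, config: SimulationConfig, truth: TruthTable
) -> dict[str, pd.DataFrame]:
    """Emit one deisotoped ion-feature table per run.

    Each detected peptide produces 1-3 co-eluting ions at consecutive scans
    centred on its (noise-shifted) NET position; ion masses carry independent
    ppm-scale errors; the summed ion intensity is the peptide's true linear
    abundance times log-normal noise.  With probability ``id_rate`` the most
    intense ion carries the peptide ID and a search score, a configurable
    fraction of which falls below the downstream score filter.
    """
    config.validate()
    if len(universe) == 0:
        raise ConfigurationError("empty peptide universe")
    design = make_design(config)
    pep = universe.peptides.set_index("peptide_seq")
    n_scans = config.n_scans
    runs: dict[str, pd.DataFrame] = {}
    for run_id in design["run_id"]:
        rng = _rng_keyed(config.seed, _STREAM_RUN, run_id)
        obs = truth.observations[truth.observations["run_id"] == run_id]
        obs = obs[obs["observed"]]
        rows: list[tuple] = []
        for seq, true_log2 in zip(obs["peptide_seq"], obs["true_log2"]):
            info = pep.loc[seq]
            n_ions = int(rng.integers(1, 4))
            eps = rng.normal(0.0, config.mass_error_ppm_sd, n_ions)
            masses = info["true_mass_da"] * (1.0 + eps * 1e-6)
            net_obs = float(np.clip(info["true_net"] + rng.normal(0.0, config.net_error_sd),
                                    0.0, 1.0))
            center = int(round(1 + net_obs * (n_scans - 1)))
            scans = np.clip(center + np.arange(n_ions) - (n_ions - 1) // 2, 1, n_scans)
            charges = rng.choice([2, 3], size=n_ions)
            total = 2.0 ** (true_log2 + rng.normal(0.0, config.intensity_noise_sd))
            weights = rng.dirichlet(np.ones(n_ions))
            intensities = np.maximum(total * weights, 1e-12)
            identified = rng.random() < config.id_rate
            top = int(np.argmax(intensities))
            if identified:
                low = rng.random() < config.low_score_rate
                score = float(rng.uniform(1.5, 2.9)) if low else float(rng.uniform(3.05, 6.0))
            for j in range(n_ions):
                rows.append(
                    (
                        run_id,
                        int(scans[j]),
                        int(charges[j]),
                        float(masses[j]),
                        float(intensities[j]),
                        seq if (identified and j == top) else None,
                        score if (identified and j == top) else np.nan,
                        info["protein_ids"] if (identified and j == top) else (),
                        seq,
                    )
                )
        df = pd.DataFrame(
            rows,
            columns=io.FEATURE_COLUMNS + ["true_peptide"],
        )
        df = df.sort_values(["scan", "monoiso_mass_da"], kind="mergesort").reset_index(drop=True)
        runs[run_id] = df
    return runs


def simulate_expression(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Gene x sample expression matrix on the linear scale.

    log2 abundance = gene baseline + planted effect (case samples only)
    + Gaussian noise; the matrix is returned exponentiated so all values
    are positive, as an abundance estimate would be.
    """
    config.validate()
    design = expression_design(config)
    if (design["group"] == GROUP_CONTROL).sum() < 2 or (design["group"] == GROUP_CASE).sum() < 2:
        raise ConfigurationError("need >= 2 samples per group for expression")
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    genes = truth.genes
    baseline = rng.normal(config.expr_baseline_log2_mean, config.expr_baseline_log2_sd,
                          len(genes))
    values = np.empty((len(genes), len(design)))
    for j, (sample, group) in enumerate(zip(design["sample"], design["group"])):
        shift = genes["effect_log2"].to_numpy() if group == GROUP_CASE else 0.0
        noise = _rng_keyed(config.seed, _STREAM_SAMPLE, sample).normal(
            0.0, config.expr_noise_sd, len(genes))
        values[:, j] = baseline + shift + noise
    return pd.DataFrame(2.0 ** values, index=pd.Index(genes["gene_id"], name="gene_id"),
                        columns=list(design["sample"]))


def make_annotation(
    truth: TruthTable,
    config: SimulationConfig,
    n_terms: int = 40,
    term_size: tuple[int, int] = (10, 80),
    n_signal_terms: int = 3,
    signal_enrichment: float = 0.6,
) -> dict[str, set[str]]:
    """Synthetic GO-like gene sets over the expressed-gene universe.

    Most terms are uniform draws; ``n_signal_terms`` terms oversample
    planted DE genes so that enrichment has something to find.
    """
    rng = _rng(config.seed, _STREAM_ANNOTATION)
    gene_ids = truth.genes["gene_id"].to_numpy()
    de_ids = truth.genes.loc[truth.genes["direction"] != "null", "gene_id"].to_numpy()
    terms: dict[str, set[str]] = {}
    lo, hi = term_size
    hi = min(hi, len(gene_ids))
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        name = f"TERM{t:04d}"
        if t <= n_signal_terms and len(de_ids) >= 2:
            n_sig = min(int(round(signal_enrichment * size)), len(de_ids))
            chosen = set(rng.choice(de_ids, size=n_sig, replace=False))
            rest = rng.choice(gene_ids, size=size, replace=False)
            chosen.update(rest[: size - n_sig])
        else:
            chosen = set(rng.choice(gene_ids, size=size, replace=False))
        terms[name] = {str(g) for g in chosen}
    return terms


def write_dataset(
    outdir: str,
    config: SimulationConfig,
    universe: PeptideUniverse,
    truth: TruthTable,
    runs: Mapping[str, pd.DataFrame],
    expression: pd.DataFrame,
    annotation: Mapping[str, set[str]] | None = None,
) -> None:
    """Write every simulated artifact as TSV (plus a YAML config echo)."""
    os.makedirs(outdir, exist_ok=True)
    io.write_design(make_design(config), os.path.join(outdir, "design.tsv"))
    io.write_design(expression_design(config), os.path.join(outdir, "expression_design.tsv"))
    for run_id, df in runs.items():
        io.write_features(df, os.path.join(outdir, f"features_{run_id}.tsv"))
    io.write_matrix(expression, os.path.join(outdir, "expression.tsv"), index_label="gene_id")
    io.write_tsv(universe.peptides, os.path.join(outdir, "truth_peptide_universe.tsv"))
    io.write_tsv(truth.proteins, os.path.join(outdir, "truth_proteins.tsv"))
    io.write_tsv(truth.genes, os.path.join(outdir, "truth_genes.tsv"))
    io.write_tsv(truth.observations, os.path.join(outdir, "truth_observations.tsv"))
    mapping = truth.proteins[["gene_id", "protein_id"]]
    io.write_tsv(mapping, os.path.join(outdir, "gene_protein_map.tsv"))
    if annotation is not None:
        io.write_gmt(annotation, os.path.join(outdir, "annotation.gmt"))
    with open(os.path.join(outdir, "config_echo.yaml"), "w") as fh:
        for key, value in asdict(config).items():
            if isinstance(value, tuple):
                value = list(value)
            fh.write(f"{key}: {value}\n")


def simulate_all(config: SimulationConfig):
    """Convenience: universe, truth, runs, expression, annotation in one call."""
    universe = generate_universe(config)
    truth = plant_truth(universe, config)
    runs = simulate_runs(universe, config, truth)
    expression = simulate_expression(config, truth)
    annotation = make_annotation(truth, config)
    return universe, truth, runs, expression, annotation
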