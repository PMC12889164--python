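"""Seeded generators for every input the screening pipeline consumes.

The real study inputs — hundreds of paired stress/control RNA-Seq runs,
database-scale predicted-structure searches, public annotation tables — are
emulated here at desk scale with known ground truth:

* expression studies with planted up/down/unchanged genes under multiplicative
  log-normal noise;
* protein pairs (a random Cα random-walk trace plus a mutated, perturbed copy)
  spanning the low-sequence/high-structure to high-sequence/high-structure
  regimes;
* Foldseek-style hit tables drawn from per-regime distributions with truth
  labels;
* domain / ortholog / cross-reference / human-score annotation tables with
  controllable evidence rates.

Every generator takes one integer seed and draws from its own named
substream, so adding a generator never shifts another's random stream, and
identical seeds reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AMINO_ACIDS, ProteinRecord
from .structure import StructureRecord, write_ca_pdb

# Fixed per-generator stream keys: a single run seed is combined with one of
# these so streams are independent and stable across versions.
_STREAMS = {
    "expression": 101,
    "protein_pair": 211,
    "hit_table": 307,
    "annotations": 401,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STREAMS[stream], int(seed)]))


# ---------------------------------------------------------------------------
# expression studies


@dataclass
class ExpressionStudy:
    """Genes x samples scaled-TPM matrix plus its stress/control pair design."""

    matrix: pd.DataFrame
    design: pd.DataFrame


REGIME_UP = "planted_up"
REGIME_DOWN = "planted_down"
REGIME_UNCHANGED = "unchanged"


def gen_expression_study(
    n_genes: int,
    n_pairs: int,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    effect_fold: float = 8.0,
    noise_sigma: float = 0.2,
    baseline_mean: float = 50.0,
    seed: int = 0,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Paired stress/control expression matrix with planted effects.

    Each gene gets a baseline abundance drawn log-normally around
    ``baseline_mean`` (between-gene spread fixed at one natural-log unit).
    Per pair, the control value is the baseline times multiplicative
    log-normal noise of scale ``noise_sigma``; the stress value is the
    control value times the gene's effect fold (``effect_fold`` for planted
    up, ``1/effect_fold`` for planted down, 1 otherwise) times independent
    noise of the same scale.  With ``noise_sigma=0`` stress is exactly
    effect-fold times control in every pair.

    Returns the study and a truth table (gene_id, regime, effect_fold).
    """
    if n_genes < 1 or n_pairs < 1:
        raise ValueError("n_genes and n_pairs must be >= 1")
    for name, frac in (("frac_up", frac_up), ("frac_down", frac_down)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    if frac_up + frac_down > 1.0:
        raise ValueError("frac_up + frac_down must be <= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if effect_fold < 1:
        raise ValueError("effect_fold must be >= 1")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")

    rng = _rng(seed, "expression")
    gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    order = rng.permutation(n_genes)
    regime = np.full(n_genes, REGIME_UNCHANGED, dtype=object)
    regime[order[:n_up]] = REGIME_UP
    regime[order[n_up : n_up + n_down]] = REGIME_DOWN
    fold = np.ones(n_genes)
    fold[regime == REGIME_UP] = effect_fold
    fold[regime == REGIME_DOWN] = 1.0 / effect_fold

    baseline = baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for k in range(n_pairs):
        ctrl_noise = rng.lognormal(0.0, noise_sigma, n_genes) if noise_sigma else 1.0
        hs_noise = rng.lognormal(0.0, noise_sigma, n_genes) if noise_sigma else 1.0
        ctrl = baseline * ctrl_noise
        hs = ctrl * fold * hs_noise
        columns[f"HS_{k:03d}"] = hs
        columns[f"NT_{k:03d}"] = ctrl
        design_rows.append((f"P{k:03d}", f"HS_{k:03d}", f"NT_{k:03d}"))

    matrix = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(design_rows, columns=["pair_id", "stress_sample", "control_sample"])
    truth = pd.DataFrame({"gene_id": gene_ids, "regime": regime, "effect_fold": fold})
    return ExpressionStudy(matrix=matrix, design=design), truth


# ---------------------------------------------------------------------------
# protein sequence/structure pairs


@dataclass
class ProteinPair:
    """A "rice" protein and its mutated, coordinate-perturbed "human" copy."""

    rice_seq: ProteinRecord
    human_seq: ProteinRecord
    rice_struct: StructureRecord
    human_struct: StructureRecord
    mapping: list[tuple[int, int]]
    truth: "ProteinPairTruth"


@dataclass(frozen=True)
class ProteinPairTruth:
    pair_id: str
    target_identity: float
    coord_noise_sigma: float
    achieved_identity: float
    regime_label: str


CA_STEP = 3.8  # Å, canonical adjacent Cα-Cα distance
CA_CLASH = 3.5  # Å, minimum allowed non-adjacent Cα-Cα distance


def _random_walk_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-step self-avoiding random walk: 3.8 Å Cα steps, rejecting any
    step that places a non-adjacent pair closer than 3.5 Å."""
    coords = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(1000):
            step = rng.normal(size=3)
            step *= CA_STEP / np.linalg.norm(step)
            candidate = coords[i - 1] + step
            if i < 2:
                break
            d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
            if d.min() >= CA_CLASH:
                break
        else:  # pragma: no cover - rejection practically always succeeds
            raise RuntimeError("backbone generation failed to place a residue")
        coords[i] = candidate
    return coords


def _regime_label(target_identity: float, coord_noise_sigma: float) -> str:
    seq = "HS" if target_identity > 0.5 else "LS"
    struct = "HS" if coord_noise_sigma <= 2.0 else "LS"
    return f"{seq}_{struct}"


def gen_protein_pair(
    length: int,
    target_identity: float = 0.3,
    coord_noise_sigma: float = 0.5,
    seed: int = 0,
    pair_id: str = "pair0",
) -> ProteinPair:
    """One synthetic cross-species protein pair with tunable divergence.

    The rice sequence is uniform over the 20 amino acids with a
    self-avoiding random-walk Cα trace; the human copy substitutes a random
    ``ceil((1 - target_identity) * length)``-residue subset (each to one of
    the 19 alternatives) and adds iid Gaussian displacement of scale
    ``coord_noise_sigma`` to every coordinate.  No indels: the residue
    mapping is the identity.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0, 1]")
    if coord_noise_sigma < 0:
        raise ValueError("coord_noise_sigma must be >= 0")

    rng = _rng(seed, "protein_pair")
    aa = np.array(list(AMINO_ACIDS))
    rice = rng.choice(aa, size=length)
    human = rice.copy()
    n_sub = int(np.ceil((1.0 - target_identity) * length))
    sites = rng.choice(length, size=n_sub, replace=False)
    for i in sites:
        alternatives = np.array([x for x in AMINO_ACIDS if x != rice[i]])
        human[i] = rng.choice(alternatives)

    rice_xyz = _random_walk_trace(length, rng)
    human_xyz = rice_xyz + (
        rng.normal(0.0, coord_noise_sigma, size=(length, 3)) if coord_noise_sigma else 0.0
    )

    achieved = 1.0 - n_sub / length
    truth = ProteinPairTruth(
        pair_id=pair_id,
        target_identity=target_identity,
        coord_noise_sigma=coord_noise_sigma,
        achieved_identity=achieved,
        regime_label=_regime_label(target_identity, coord_noise_sigma),
    )
    return ProteinPair(
        rice_seq=ProteinRecord(f"{pair_id}_rice", "".join(rice)),
        human_seq=ProteinRecord(f"{pair_id}_human", "".join(human)),
        rice_struct=StructureRecord(f"{pair_id}_rice", rice_xyz),
        human_struct=StructureRecord(f"{pair_id}_human", human_xyz),
        mapping=[(i, i) for i in range(length)],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# hit tables

# Per-regime (mean, sd) for similarity %, average lDDT and both coverages.
# Means are well separated so midpoint thresholds recover the truth labels.
DEFAULT_REGIME_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "LS_HS": {"similarity": (15.0, 5.0), "lddt": (0.85, 0.04), "qcov": (0.9, 0.05), "tcov": (0.9, 0.05)},
    "HS_HS": {"similarity": (70.0, 8.0), "lddt": (0.85, 0.04), "qcov": (0.9, 0.05), "tcov": (0.9, 0.05)},
    "LS_LS": {"similarity": (15.0, 5.0), "lddt": (0.30, 0.06), "qcov": (0.9, 0.05), "tcov": (0.9, 0.05)},
    "HS_LS": {"similarity": (70.0, 8.0), "lddt": (0.30, 0.06), "qcov": (0.9, 0.05), "tcov": (0.9, 0.05)},
}

_FIELD_BOUNDS = {"similarity": (0.0, 100.0), "lddt": (0.0, 1.0), "qcov": (1e-6, 1.0), "tcov": (1e-6, 1.0)}


def gen_hit_table(
    n_per_regime: int | dict[str, int],
    regime_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Structural hit-pair table drawn from per-regime distributions.

    Each row carries a distinct rice gene/accession, a human accession, both
    coverages, average lDDT and global sequence similarity, plus a
    ``truth_regime`` column.  Gaussian draws are clipped to the valid range
    of each field.  ``n_per_regime`` may be one count for all regimes or a
    per-regime mapping; zero counts yield an empty table without error.
    """
    params = DEFAULT_REGIME_PARAMS if regime_params is None else regime_params
    if not params:
        raise ValueError("regime parameter set must not be empty")
    if isinstance(n_per_regime, int):
        counts = {regime: n_per_regime for regime in params}
    else:
        counts = dict(n_per_regime)
        unknown = set(counts) - set(params)
        if unknown:
            raise KeyError(f"counts given for unknown regimes: {sorted(unknown)}")
    for regime, spec in params.items():
        for fieldname, (mean, sd) in spec.items():
            lo, hi = _FIELD_BOUNDS[fieldname]
            if not lo <= mean <= hi or sd < 0:
                raise ValueError(f"{regime}.{fieldname}: mean outside [{lo}, {hi}] or sd < 0")

    rng = _rng(seed, "hit_table")
    rows = []
    idx = 0
    for regime in sorted(counts):
        spec = params[regime]
        for _ in range(counts[regime]):
            row = {"rice_gene_id": f"OsG{idx:05d}", "rice_accession": f"RACC{idx:05d}",
                   "human_accession": f"HACC{idx:05d}"}
            for fieldname, col in (("qcov", "qcov"), ("tcov", "tcov"),
                                   ("lddt", "avg_lddt"), ("similarity", "seq_similarity_pct")):
                mean, sd = spec[fieldname]
                lo, hi = _FIELD_BOUNDS[fieldname]
                row[col] = float(np.clip(rng.normal(mean, sd), lo, hi))
            row["truth_regime"] = regime
            rows.append(row)
            idx += 1
    columns = ["rice_gene_id", "rice_accession", "human_accession", "qcov", "tcov",
               "avg_lddt", "seq_similarity_pct", "truth_regime"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# annotation tables


@dataclass
class AnnotationBundle:
    """Domain, ortholog, cross-reference and human HN-score tables."""

    domains: pd.DataFrame  # accession, interpro_id
    orthologs: pd.DataFrame  # rice_gene_id, human_gene_symbol
    xref: pd.DataFrame  # human_accession, ensembl_gene_id, gene_symbol
    human_scores: pd.DataFrame  # gene_symbol, hn_score


def gen_annotations(
    pairs: pd.DataFrame,
    p_shared_domain: float = 0.5,
    p_ortholog: float = 0.3,
    n_human_genes: int = 10_000,
    seed: int = 0,
) -> AnnotationBundle:
    """Annotation tables consistent with a hit-pair table.

    Every accession gets 0-3 background domain IDs; with probability
    ``p_shared_domain`` a pair additionally receives a common ID on both
    sides.  With probability ``p_ortholog`` the pair's (rice gene, human
    symbol) enters the ortholog table.  Human gene symbols are drawn without
    replacement from a universe of ``n_human_genes`` symbols, each with an
    integer human HN-score; the xref table maps every human accession
    unambiguously to its symbol.
    """
    for name, p in (("p_shared_domain", p_shared_domain), ("p_ortholog", p_ortholog)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if n_human_genes < len(pairs):
        raise ValueError("n_human_genes must cover the distinct human accessions")

    rng = _rng(seed, "annotations")
    symbols = [f"HGNC{i:05d}" for i in range(n_human_genes)]
    human_scores = pd.DataFrame(
        {"gene_symbol": symbols, "hn_score": rng.integers(-204, 256, size=n_human_genes)}
    )

    human_accs = list(dict.fromkeys(pairs["human_accession"])) if len(pairs) else []
    chosen = rng.choice(n_human_genes, size=len(human_accs), replace=False)
    xref = pd.DataFrame(
        {
            "human_accession": human_accs,
            "ensembl_gene_id": [f"ENSG{i:011d}" for i in chosen],
            "gene_symbol": [symbols[i] for i in chosen],
        }
    )
    symbol_of = dict(zip(xref["human_accession"], xref["gene_symbol"]))

    domain_rows = []
    accessions = list(dict.fromkeys(list(pairs.get("rice_accession", [])) + human_accs))
    for acc in accessions:
        for _ in range(int(rng.integers(0, 4))):
            domain_rows.append((acc, f"IPR9{int(rng.integers(0, 100_000)):05d}"))

    ortholog_rows = []
    for i, row in enumerate(pairs.itertuples(index=False)):
        if rng.random() < p_shared_domain:
            shared_id = f"IPRS{i:05d}"
            domain_rows.append((row.rice_accession, shared_id))
            domain_rows.append((row.human_accession, shared_id))
        if rng.random() < p_ortholog:
            ortholog_rows.append((row.rice_gene_id, symbol_of[row.human_accession]))

    domains = pd.DataFrame(domain_rows, columns=["accession", "interpro_id"]).drop_duplicates(
        ignore_index=True
    )
    orthologs = pd.DataFrame(
        ortholog_rows, columns=["rice_gene_id", "human_gene_symbol"]
    ).drop_duplicates(ignore_index=True)
    return AnnotationBundle(domains=domains, orthologs=orthologs, xref=xref, human_scores=human_scores)


# ---------------------------------------------------------------------------
# writers


def write_expression_study(study: ExpressionStudy, truth: pd.DataFrame, outdir, prefix: str = "study") -> dict[str, str]:
    """Write matrix / design / truth TSVs; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}_matrix.tsv",
        "design": outdir / f"{prefix}_design.tsv",
        "truth": outdir / f"{prefix}_truth.tsv",
    }
    study.matrix.to_csv(paths["matrix"], sep="\t")
    study.design.to_csv(paths["design"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_protein_pair(pair: ProteinPair, outdir) -> dict[str, str]:
    """Write FASTA (both sequences) and two Cα-only PDB files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{pair.truth.pair_id}.fasta"
    with open(fasta, "w") as fh:
        for rec in (pair.rice_seq, pair.human_seq):
            fh.write(f">{rec.accession}\n{rec.sequence}\n")
    rice_pdb = outdir / f"{pair.truth.pair_id}_rice.pdb"
    human_pdb = outdir / f"{pair.truth.pair_id}_human.pdb"
    write_ca_pdb(pair.rice_struct, rice_pdb, pair.rice_seq.sequence)
    write_ca_pdb(pair.human_struct, human_pdb, pair.human_seq.sequence)
    return {"fasta": str(fasta), "rice_pdb": str(rice_pdb), "human_pdb": str(human_pdb)}
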