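"""Synthetic worlds with planted ground truth.

The generator emulates the structure of the real training corpora at a
configurable desk scale:

- *basal profiles*: cells live in well-separated latent clusters; a linear
  gene-loading map plus i.i.d. noise turns the latent state into a
  log-scale expression profile, so a profile-driven encoder can recover the
  latent cell state.
- *perturbation responses*: the differential expression of (drug, cell,
  dose) is a smooth low-rank bilinear function — a drug main effect plus a
  drug-by-cell interaction in latent space — scaled by a saturating
  (Hill-family) dose factor. Drug latent factors are deterministic
  functions of molecular-graph invariants, so the chemical-graph branch of
  a model has real signal to learn.
- *replicates*: each condition yields several noisy replicates; a chosen
  fraction is corrupted with extra noise so its average inter-replicate
  correlation falls below the reliability cutoff (the low-quality pool).
- *viability*: Hill curves whose asymptote depends on the same drug-cell
  latent compatibility, so transcriptomic and viability tasks share
  structure.
- *patients*: perturbed cell profiles with up/down disease signatures
  constructed to be partially reversed by one planted library drug (its
  profile suppresses the patient's up-genes strongly and induces the
  down-genes mildly).

Every generator output is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem_graph
from .data_core import DoseResponsePoint, ExpressionMatrix, ReplicateSet
from .dose_response import HillParams, hill_viability
from .repurposing import PatientSignature, RankedProfile

# 100 valid drug-like and fragment SMILES used as the compound library.
SMILES_LIBRARY = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "c1ccc2c(c1)cccc2",                 # naphthalene
    "c1ccc(cc1)c1ccccc1",               # biphenyl
    "Clc1ccccc1",
    "Brc1ccccc1",
    "Fc1ccc(F)cc1",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "COc1ccccc1",
    "CCOc1ccccc1",
    "Cc1ccccc1C",
    "Cc1cccc(C)c1",
    "CC(C)c1ccccc1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "c1cnc2[nH]ccc2c1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2occc2c1",
    "c1ccc2sccc2c1",
    "O=C(O)c1ccccc1",
    "O=C(N)c1ccccc1",
    "N#Cc1ccccc1",
    "O=[N+]([O-])c1ccccc1",
    "CC(=O)c1ccccc1",
    "OCc1ccccc1",
    "NCc1ccccc1",
    "O=Cc1ccccc1",
    "CC(N)C(=O)O",
    "NC(CO)C(=O)O",
    "NC(Cc1ccccc1)C(=O)O",
    "NC(CS)C(=O)O",
    "OC(=O)CCC(=O)O",
    "OC(=O)C=CC(=O)O",
    "OC(=O)c1ccccc1O",
    "OC(=O)c1ccc(O)cc1",
    "CCCCCC",
    "CCCCCCCC",
    "CCCCCCCCCC",
    "CC(C)CC(C)C",
    "C1CCCCC1",
    "C1CCCC1",
    "C1CCCCCC1",
    "C1CCC2CCCCC2C1",
    "CC1CCCCC1",
    "OC1CCCCC1",
    "NC1CCCCC1",
    "O=C1CCCCC1",
    "C1CCOC1",
    "C1CCNC1",
    "C1CCSC1",
    "C1COCCN1",
    "C1CNCCN1",
    "O1CCOCC1",
    "CN1CCNCC1",
    "CN1CCOCC1",
    "CCN(CC)CC",
    "CC(C)N",
    "CCCN",
    "CCCCN",
    "CCO",
    "CCCO",
    "CC(C)O",
    "CC(C)(C)O",
    "CCOCC",
    "CCSC",
    "CC(=O)C",
    "CC(=O)CC",
    "CCC(=O)O",
    "CCCC(=O)O",
    "CC(=O)OC",
    "CC(=O)OCC",
    "CC(=O)N",
    "CC(=O)NC",
    "CN(C)C=O",
    "CS(=O)C",
    "CS(=O)(=O)O",
    "NS(=O)(=O)c1ccccc1",
    "COc1ccc(CCN)cc1",
    "NCCc1ccccc1",
    "NCCc1c[nH]c2ccccc12",
    "NCCc1ccc(O)c(O)c1",
    "CNC(C)Cc1ccccc1",
    "CC(N)Cc1ccccc1",
    "Oc1ccc(CCN)cc1",
    "COc1cc2c(cc1OC)CCN2",
    "CN1CCC(CC1)c1ccccc1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "O=C(Oc1ccccc1)c1ccccc1",
    "c1ccc(cc1)Cc1ccccc1",
    "c1ccc(cc1)Oc1ccccc1",
    "c1ccc(cc1)Sc1ccccc1",
    "c1ccc(cc1)Nc1ccccc1",
    "CC(C)(C)c1ccccc1",
    "CCc1ccccc1",
    "C=Cc1ccccc1",
]


@dataclass
class WorldSpec:
    """Study conditions for one synthetic world (desk-scale defaults)."""

    n_genes: int = 150
    n_cells: int = 40
    n_clusters: int = 8
    n_drugs: int = 30
    doses: tuple = (0.1, 0.5, 1.0, 5.0, 10.0)  # uM
    latent_dim: int = 6
    cluster_scale: float = 2.5       # separation of cluster centers in latent space
    within_cluster_std: float = 0.5
    profile_noise_std: float = 0.3   # measurement noise on basal profiles
    basal_mean: float = 5.0          # log2-TPM-like offset
    interaction_strength: float = 1.0  # drug-by-cell term relative to drug main effect
    replicate_noise_std: float = 0.3
    corruption_noise_std: float = 1.5
    n_replicates: int = 3
    low_quality_fraction: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_cells:
            raise ValueError("n_clusters cannot exceed n_cells")
        if self.n_drugs > len(SMILES_LIBRARY):
            raise ValueError(f"at most {len(SMILES_LIBRARY)} library drugs available")
        if min(self.n_genes, self.n_cells, self.n_clusters, self.n_drugs) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class PlantedTruth:
    """Ground-truth latent state of a generated world."""

    spec: WorldSpec
    gene_ids: list[str]
    cell_ids: list[str]
    cell_latents: dict[str, np.ndarray]
    cell_clusters: dict[str, int]
    drug_ids: list[str]
    smiles: dict[str, str]
    drug_factors: dict[str, np.ndarray]
    loading_basal: np.ndarray     # (G, r)
    loading_main: np.ndarray      # (G, r)
    loading_interact: np.ndarray  # (G, r)
    dose_k: dict[str, float]      # half-saturation dose per drug
    dose_h: dict[str, float]      # dose-factor steepness per drug
    hill: dict[tuple, HillParams] # (drug, cell) -> viability curve

    def dose_factor(self, drug_id: str, dose: float) -> float:
        k, h = self.dose_k[drug_id], self.dose_h[drug_id]
        return dose**h / (dose**h + k**h)

    def dgx_for_latent(self, drug_id: str, latent: np.ndarray, dose: float) -> np.ndarray:
        """Noiseless differential expression for an arbitrary cell latent."""
        a = self.drug_factors[drug_id]
        main = self.loading_main @ a
        inter = self.loading_interact @ (a * latent)
        return self.dose_factor(drug_id, dose) * (
            main + self.spec.interaction_strength * inter)

    def true_dgx(self, drug_id: str, cell_id: str, dose: float) -> np.ndarray:
        return self.dgx_for_latent(drug_id, self.cell_latents[cell_id], dose)

    def true_viability(self, drug_id: str, cell_id: str, dose: float) -> float:
        return float(hill_viability(self.hill[(drug_id, cell_id)], dose))


def _graph_invariants(smiles: str) -> np.ndarray:
    g = chem_graph.smiles_to_graph(smiles)
    feats = g.atom_features
    nv = len(chem_graph.ATOM_VOCAB)
    elem_counts = feats[:, :nv].sum(axis=0)
    return np.array([
        g.n_atoms,
        len(g.bonds),
        len(g.bonds) - g.n_atoms + 1,           # cycle rank (connected molecules)
        feats[:, nv + chem_graph.MAX_DEGREE + 1].sum(),  # aromatic atoms
        elem_counts[0], elem_counts[1], elem_counts[2],  # C, N, O
        elem_counts[3:8].sum(),                  # S + halogens
        feats[:, nv:nv + chem_graph.MAX_DEGREE + 1].argmax(axis=1).mean(),
        float(feats[:, -1].sum()),               # net formal charge
    ])


def make_world(spec: WorldSpec) -> tuple[ExpressionMatrix, list[dict], PlantedTruth]:
    """Generate basal profiles, a drug table and the planted truth."""
    rng = np.random.default_rng(spec.rng_seed)
    g, r = spec.n_genes, spec.latent_dim
    gene_ids = [f"g{i}" for i in range(g)]
    cell_ids = [f"cell{i}" for i in range(spec.n_cells)]

    centers = rng.normal(0.0, spec.cluster_scale, size=(spec.n_clusters, r))
    # round-robin assignment keeps clusters near-balanced
    cluster_of = {c: i % spec.n_clusters for i, c in enumerate(cell_ids)}
    cell_latents = {
        c: centers[cluster_of[c]] + rng.normal(0.0, spec.within_cluster_std, size=r)
        for c in cell_ids
    }

    loading_basal = rng.normal(0.0, 1.0 / np.sqrt(r), size=(g, r))
    loading_main = rng.normal(0.0, 1.0 / np.sqrt(r), size=(g, r))
    loading_interact = rng.normal(0.0, 1.0 / np.sqrt(r), size=(g, r))

    basal = np.empty((g, spec.n_cells))
    for j, c in enumerate(cell_ids):
        basal[:, j] = (spec.basal_mean + loading_basal @ cell_latents[c]
                       + rng.normal(0.0, spec.profile_noise_std, size=g))
    basal_matrix = ExpressionMatrix(gene_ids=gene_ids, sample_ids=cell_ids,
                                    values=basal, space_tag="log2")

    drug_ids = [f"drug{i}" for i in range(spec.n_drugs)]
    smiles = dict(zip(drug_ids, SMILES_LIBRARY[: spec.n_drugs]))
    inv = np.stack([_graph_invariants(smiles[d]) for d in drug_ids])
    inv = (inv - inv.mean(axis=0)) / np.where(inv.std(axis=0) == 0, 1.0, inv.std(axis=0))
    proj = rng.normal(0.0, 1.0, size=(inv.shape[1], r)) / np.sqrt(inv.shape[1])
    factors = inv @ proj
    norms = np.linalg.norm(factors, axis=1, keepdims=True)
    factors = factors / np.where(norms == 0, 1.0, norms) * np.sqrt(r)
    drug_factors = dict(zip(drug_ids, factors))

    lo, hi = min(spec.doses), max(spec.doses)
    dose_k = {d: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for d in drug_ids}
    dose_h = {d: float(rng.uniform(0.8, 2.0)) for d in drug_ids}

    hill: dict[tuple, HillParams] = {}
    for d in drug_ids:
        for c in cell_ids:
            compat = float(drug_factors[d] @ cell_latents[c]) / r
            einf = 0.15 + 0.7 / (1.0 + np.exp(-compat))  # latent-tied asymptote
            hill[(d, c)] = HillParams(E0=1.0, Einf=float(einf),
                                      EC50=dose_k[d], H=dose_h[d])

    truth = PlantedTruth(
        spec=spec, gene_ids=gene_ids, cell_ids=cell_ids,
        cell_latents=cell_latents, cell_clusters=cluster_of,
        drug_ids=drug_ids, smiles=smiles, drug_factors=drug_factors,
        loading_basal=loading_basal, loading_main=loading_main,
        loading_interact=loading_interact, dose_k=dose_k, dose_h=dose_h,
        hill=hill,
    )
    drug_table = [{"drug_id": d, "smiles": smiles[d]} for d in drug_ids]
    return basal_matrix, drug_table, truth


def make_perturbation_dataset(truth: PlantedTruth, seed: int | None = None,
                              cells_per_drug: int | None = None,
                              doses_per_pair: int | None = None
                              ) -> list[ReplicateSet]:
    """Replicated perturbation measurements with a planted low-quality pool.

    A ``low_quality_fraction`` of (drug, cell, dose) conditions receives
    extra corruption noise so its average replicate correlation drops below
    the reliability cutoff. ``cells_per_drug``/``doses_per_pair`` subsample
    the condition grid for faster training runs.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.rng_seed + 1 if seed is None else seed)
    sets: list[ReplicateSet] = []
    for d in truth.drug_ids:
        cells = list(truth.cell_ids)
        if cells_per_drug is not None and cells_per_drug < len(cells):
            cells = [cells[i] for i in rng.choice(len(cells), size=cells_per_drug,
                                                  replace=False)]
        for c in cells:
            doses = list(spec.doses)
            if doses_per_pair is not None and doses_per_pair < len(doses):
                doses = [doses[i] for i in
                         sorted(rng.choice(len(doses), size=doses_per_pair,
                                           replace=False))]
            for dose in doses:
                clean = truth.true_dgx(d, c, dose)
                corrupt = rng.random() < spec.low_quality_fraction
                std = spec.corruption_noise_std if corrupt else spec.replicate_noise_std
                reps = [clean + rng.normal(0.0, std, size=clean.shape)
                        for _ in range(spec.n_replicates)]
                sets.append(ReplicateSet(key=(d, c, dose, 24.0), replicates=reps,
                                         smiles=truth.smiles[d]))
    return sets


def make_unlabeled_profiles(truth: PlantedTruth, n: int, seed: int | None = None
                            ) -> np.ndarray:
    """Extra basal profiles (n x G) without perturbation labels.

    Emulates the large heterogeneous expression compendium available for
    autoencoder training: same cluster mixture as the world's cells, fresh
    draws.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.rng_seed + 5 if seed is None else seed)
    centers = np.stack([truth.cell_latents[c] - 0.0 for c in truth.cell_ids])
    # re-derive cluster centers from the planted assignment
    uniq = sorted(set(truth.cell_clusters.values()))
    cmeans = np.stack([
        np.mean([truth.cell_latents[c] for c in truth.cell_ids
                 if truth.cell_clusters[c] == k], axis=0) for k in uniq])
    out = np.empty((n, spec.n_genes))
    for i in range(n):
        k = int(rng.integers(len(uniq)))
        lat = cmeans[k] + rng.normal(0.0, spec.within_cluster_std, size=spec.latent_dim)
        out[i] = (spec.basal_mean + truth.loading_basal @ lat
                  + rng.normal(0.0, spec.profile_noise_std, size=spec.n_genes))
    return out


def make_viability_dataset(truth: PlantedTruth, seed: int | None = None,
                           noise_std: float = 0.02) -> list[DoseResponsePoint]:
    """Viability measurements on the world's dose grid."""
    spec = truth.spec
    rng = np.random.default_rng(spec.rng_seed + 2 if seed is None else seed)
    pts = []
    for d in truth.drug_ids:
        for c in truth.cell_ids:
            for dose in spec.doses:
                v = truth.true_viability(d, c, dose) + rng.normal(0.0, noise_std)
                pts.append(DoseResponsePoint(d, c, float(dose), float(v)))
    return pts


def make_patient_cohort(truth: PlantedTruth, n_patients: int = 5,
                        n_library_drugs: int = 50, n_up: int = 12,
                        n_down: int = 12, signature_dose: float | None = None,
                        toxic_drug: bool = True, seed: int | None = None):
    """Patients with signatures partially reversed by one planted drug each.

    Returns (patients, signatures, drug_profiles, viability_curves, planted)
    where ``planted`` maps patient_id -> its reversal drug, and
    ``drug_profiles`` holds each library drug's induced profile per patient
    (patient-specific, from the patient's latent state).

    The signature is built from the planted drug's profile: the up-genes
    are the genes that drug suppresses most strongly (deep bottom of the
    ranking), and the down-genes are spread over the upper ranks so the
    drug induces them mildly — a partial reversal. One library drug is
    optionally made toxic (viability 0.4 at 1 uM); planted reversal drugs
    are always safe (flat viability near 0.95).
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.rng_seed + 3 if seed is None else seed)
    if n_library_drugs > len(SMILES_LIBRARY):
        raise ValueError("library exceeds packaged SMILES list")
    dose_ref = signature_dose or max(spec.doses)
    lib_ids = [f"lib{i}" for i in range(n_library_drugs)]
    lib_smiles = dict(zip(lib_ids, SMILES_LIBRARY[:n_library_drugs]))
    inv = np.stack([_graph_invariants(lib_smiles[d]) for d in lib_ids])
    inv = (inv - inv.mean(axis=0)) / np.where(inv.std(axis=0) == 0, 1.0, inv.std(axis=0))
    proj = rng.normal(0.0, 1.0, size=(inv.shape[1], spec.latent_dim)) / np.sqrt(inv.shape[1])
    factors = inv @ proj
    # jitter breaks exact degeneracies between isomer-like molecules whose
    # graph invariants coincide
    factors = factors + 0.2 * rng.normal(size=factors.shape)
    norms = np.linalg.norm(factors, axis=1, keepdims=True)
    factors = factors / np.where(norms == 0, 1.0, norms) * np.sqrt(spec.latent_dim)
    lib_factors = dict(zip(lib_ids, factors))

    patients = {}
    signatures = []
    drug_profiles: dict[str, dict[str, RankedProfile]] = {}
    viability_curves: dict[str, HillParams] = {}
    planted: dict[str, str] = {}
    toxic_id = lib_ids[-1] if toxic_drug else None

    base_truth_factors = dict(truth.drug_factors)
    for pi in range(n_patients):
        pid = f"patient{pi}"
        host = truth.cell_ids[int(rng.integers(len(truth.cell_ids)))]
        latent = truth.cell_latents[host] + rng.normal(0.0, 0.3, size=spec.latent_dim)
        patients[pid] = (spec.basal_mean + truth.loading_basal @ latent
                         + rng.normal(0.0, spec.profile_noise_std, size=spec.n_genes))
        # per-patient induced profiles of the whole library
        profs = {}
        for d in lib_ids:
            a = lib_factors[d]
            vals = (truth.loading_main @ a
                    + spec.interaction_strength * (truth.loading_interact @ (a * latent)))
            profs[d] = RankedProfile(gene_ids=list(truth.gene_ids), values=vals)
        drug_profiles[pid] = profs
        # planted reversal drug: never the toxic one
        choices = [d for d in lib_ids if d != toxic_id]
        pdrug = choices[int(rng.integers(len(choices)))]
        planted[pid] = pdrug
        vals = profs[pdrug].values
        order = np.argsort(vals, kind="stable")
        up_genes = {truth.gene_ids[i] for i in order[:n_up]}  # most suppressed
        # down-genes slightly above the uniform diagonal of the ranking:
        # every running-statistic value is a small positive number, so the
        # ES is mildly positive (weak induction) and sign-stable
        m = spec.n_genes
        positions = np.minimum((np.arange(n_down) + 0.5) / n_down + 0.08, 0.99)
        down_idx = []
        taken = set(order[:n_up])
        for q in positions:
            j = int(q * (m - 1))
            while order[j] in taken:  # avoid collisions with up set
                j -= 1
            down_idx.append(order[j])
            taken.add(order[j])
        down_genes = {truth.gene_ids[i] for i in down_idx}
        signatures.append(PatientSignature(patient_id=pid, up_genes=up_genes,
                                           down_genes=down_genes))
    for d in lib_ids:
        a = lib_factors[d]
        compat = float(a @ a) / spec.latent_dim
        einf = 0.5 + 0.45 / (1.0 + np.exp(-compat))
        viability_curves[d] = HillParams(E0=1.0, Einf=float(einf), EC50=5.0, H=1.0)
    for pid, pdrug in planted.items():
        viability_curves[pdrug] = HillParams(E0=1.0, Einf=0.95, EC50=5.0, H=1.0)
    if toxic_id is not None:
        # viability exactly 0.4 at 1 uM: 1 - 0.7/(1 + 1/6) = 0.4
        viability_curves[toxic_id] = HillParams(E0=1.0, Einf=0.3, EC50=1.0 / 6.0, H=1.0)
    return patients, signatures, drug_profiles, viability_curves, planted
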