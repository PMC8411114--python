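"""Synthetic MaxQuant-dialect data with known ground truth.

The generator emulates the statistical structure of the study design —
treatments {bic, ttx, control} x timepoints {5min, 15min, 24h} x 4
biological x 3 technical replicates — at the level the pipeline consumes:
phosphosite and protein-groups tables, a design table and a truth table.

For each phospho-event and sample the log2 intensity is

    y = baseline + b_biorep + Delta(condition, profile) + eps

with one random intercept ``b ~ N(0, sigma_b^2)`` per (event, biological
replicate) shared across all samples of that replicate (this is what makes
the paired treated/control design informative, exactly as the fitted mixed
model assumes), and ``eps ~ N(0, sigma_e^2)`` per cell.  Planted effect
profiles are step functions over the three timepoints:

* ``early``     - effect at 5 min and 15 min, one treatment;
* ``late``      - effect at 24 h, one treatment;
* ``persistent``- effect at all timepoints, one treatment;
* ``persistent_reciprocal`` - persistent in both treatments with opposite
  signs;
* ``exclusive`` - present in all biological replicates of exactly one
  treated condition and unreliable everywhere else (never testable);
* ``null``      - no effect.

Missingness is the union of a completely-at-random component and an
intensity-dependent (missing-not-at-random) component with
``P(missing | y) = 1 / (1 + exp((y - y0) / s))``.  Decoy rows carry
``REV__`` accessions, contaminant rows ``CON__``; a configurable fraction
of rows fails the class-I localization filter.  All randomness derives
from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import io as pio
from .io import SampleDesign, SiteRecord, ProteinRecord, KinaseSubstrateRelation, GeneSet
from .preprocess import CONDITIONS

PROFILES = ("null", "early", "late", "persistent", "persistent_reciprocal", "exclusive")

#: timepoints at which each profile's effect is active
ACTIVE_TIMEPOINTS = {
    "early": ("5min", "15min"),
    "late": ("24h",),
    "persistent": ("5min", "15min", "24h"),
    "persistent_reciprocal": ("5min", "15min", "24h"),
}

RESIDUE_PROBS = {"S": 0.80, "T": 0.18, "Y": 0.02}


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic experiment (~2,000 events)."""

    n_proteins: int = 500
    mean_sites_per_protein: float = 3.0
    #: probability that multiplicity slot 1/2/3 of a site row is populated
    multiplicity_probs: tuple[float, float, float] = (1.0, 0.25, 0.05)
    baseline_mean: float = 23.0
    baseline_sd: float = 2.0
    sigma_b: float = 0.25
    sigma_e: float = 0.2
    effect_low: float = 0.5
    effect_high: float = 1.5
    profile_mix: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.80,
            "early": 0.05,
            "late": 0.05,
            "persistent": 0.04,
            "persistent_reciprocal": 0.04,
            "exclusive": 0.02,
        }
    )
    mcar_rate: float = 0.02
    mnar_midpoint: float = 20.0
    mnar_slope: float = 1.0
    class1_prob: float = 0.85
    decoy_rate: float = 0.01
    contaminant_rate: float = 0.01
    n_bio: int = 4
    n_tech: int = 3
    protein_regulated_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.profile_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"profile_mix proportions sum to {total}, not 1")
        if set(self.profile_mix) - set(PROFILES):
            raise ConfigError(f"unknown profiles {set(self.profile_mix) - set(PROFILES)}")
        if self.sigma_b < 0 or self.sigma_e <= 0 or self.baseline_sd <= 0:
            raise ConfigError("SDs must be positive")
        if self.profile_mix.get("exclusive", 0) > 0 and self.n_bio < 4:
            raise ConfigError("exclusive profiles require >= 4 biological replicates")


@dataclass
class SimResult:
    """File paths and in-memory truth of one simulated experiment."""

    design: list[SampleDesign]
    sites_path: Path
    proteins_path: Path
    design_path: Path
    truth_path: Path
    protein_truth_path: Path
    truth: pd.DataFrame
    protein_truth: pd.DataFrame


def _draw_profiles(rng: np.random.Generator, n: int, mix: dict[str, float]) -> np.ndarray:
    names = sorted(mix)
    probs = np.array([mix[k] for k in names])
    return rng.choice(names, size=n, p=probs / probs.sum())


def _mnar_missing(rng: np.random.Generator, y: np.ndarray, y0: float, s: float) -> np.ndarray:
    p_missing = 1.0 / (1.0 + np.exp((y - y0) / s))
    return rng.random(y.shape) < p_missing


def simulate_experiment(config: SimConfig, outdir: str | Path) -> SimResult:
    """Generate the full synthetic experiment and write all input files.

    Writes ``phospho_sites.tsv``, ``protein_groups.tsv``, ``design.tsv``,
    ``truth.tsv`` and ``protein_truth.tsv`` into ``outdir``.  Identical
    configs (including seed) produce byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = pio.default_design(n_bio=config.n_bio, n_tech=config.n_tech)

    # ---- site/event layout -------------------------------------------------
    n_sites_per_protein = 1 + rng.poisson(max(config.mean_sites_per_protein - 1.0, 0.0), config.n_proteins)
    residues = np.array(list(RESIDUE_PROBS))
    res_p = np.array(list(RESIDUE_PROBS.values()))

    site_rows = []  # (protein, gene, position, residue, [slots])
    for i in range(config.n_proteins):
        protein = f"P{i + 1:05d}"
        gene = f"Gene{i + 1}"
        positions = rng.choice(np.arange(1, 2001), size=n_sites_per_protein[i], replace=False)
        for pos in np.sort(positions):
            residue = str(rng.choice(residues, p=res_p))
            slots = [k + 1 for k in range(3) if rng.random() < config.multiplicity_probs[k]]
            if not slots:
                slots = [1]
            site_rows.append((protein, gene, int(pos), residue, slots))

    # class-I status is a property of the site row (its localization prob)
    class1 = rng.random(len(site_rows)) < config.class1_prob
    loc_probs = np.where(
        class1,
        rng.uniform(0.755, 1.0, len(site_rows)),
        rng.uniform(0.05, 0.745, len(site_rows)),
    )

    # enumerate events = populated slots of class-I rows; assign profiles
    event_index = []  # (row_idx, slot)
    for ri, (_, _, _, _, slots) in enumerate(site_rows):
        for k in slots:
            event_index.append((ri, k))
    event_is_truth = np.array([class1[ri] for ri, _ in event_index])
    n_events = len(event_index)
    profiles = np.where(event_is_truth, _draw_profiles(rng, n_events, config.profile_mix), "null")

    # planted effects
    sizes = rng.uniform(config.effect_low, config.effect_high, n_events)
    signs = rng.choice([-1.0, 1.0], n_events)
    assigned_trt = rng.choice(["bic", "ttx"], n_events)
    exclusive_cond = [CONDITIONS[j] for j in rng.integers(0, len(CONDITIONS), n_events)]

    deltas = {c: np.zeros(n_events) for c in CONDITIONS}
    for e in range(n_events):
        prof = profiles[e]
        if prof in ("early", "late", "persistent"):
            for tp in ACTIVE_TIMEPOINTS[prof]:
                deltas[(assigned_trt[e], tp)][e] = signs[e] * sizes[e]
        elif prof == "persistent_reciprocal":
            for tp in ACTIVE_TIMEPOINTS[prof]:
                deltas[("bic", tp)][e] = signs[e] * sizes[e]
                deltas[("ttx", tp)][e] = -signs[e] * sizes[e]

    # ---- intensities -------------------------------------------------------
    sample_order = [d.sample_id for d in design]
    n_samples = len(sample_order)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_events)
    b = rng.normal(0.0, config.sigma_b, (n_events, config.n_bio))
    eps = rng.normal(0.0, config.sigma_e, (n_events, n_samples))

    log2y = np.empty((n_events, n_samples))
    for j, d in enumerate(design):
        col = baseline + b[:, d.bio_rep - 1] + eps[:, j]
        if d.treatment in ("bic", "ttx"):
            col = col + deltas[(d.treatment, d.timepoint)]
        log2y[:, j] = col

    # ---- missingness -------------------------------------------------------
    missing = _mnar_missing(rng, log2y, config.mnar_midpoint, config.mnar_slope)
    missing |= rng.random(log2y.shape) < config.mcar_rate

    # exclusive events: structural presence/absence pattern
    group_cols: dict[tuple[str, str], list[int]] = {}
    for j, d in enumerate(design):
        group_cols.setdefault((d.treatment, d.timepoint), []).append(j)
    dropped_bio = rng.integers(1, config.n_bio + 1, (n_events, len(group_cols)))
    group_list = sorted(group_cols)
    for e in range(n_events):
        if profiles[e] != "exclusive":
            continue
        c = exclusive_cond[e]
        for gi, g in enumerate(group_list):
            cols = group_cols[g]
            if g == c:
                # guarantee detection in every biological replicate
                for bio in range(1, config.n_bio + 1):
                    tech1 = [j for j in cols if design[j].bio_rep == bio][0]
                    missing[e, tech1] = False
            else:
                # knock out one whole biological replicate -> fails 4-of-4
                drop = dropped_bio[e, gi]
                for j in cols:
                    if design[j].bio_rep == drop:
                        missing[e, j] = True

    # ---- assemble site records --------------------------------------------
    records: list[SiteRecord] = []
    truth_rows = []
    for ri, (protein, gene, pos, residue, slots) in enumerate(site_rows):
        intensities: dict[tuple[str, int], float] = {}
        for e, (ri2, k) in enumerate(event_index):
            if ri2 != ri:
                continue
            for j, sid in enumerate(sample_order):
                if not missing[e, j]:
                    intensities[(sid, k)] = float(2.0 ** log2y[e, j])
            if event_is_truth[e] and not missing[e].all():
                row = {
                    "protein": protein,
                    "position": pos,
                    "residue": residue,
                    "multiplicity": k,
                    "gene_name": gene,
                    "profile": profiles[e],
                    "treatment": (
                        "both"
                        if profiles[e] == "persistent_reciprocal"
                        else (assigned_trt[e] if profiles[e] in ("early", "late", "persistent") else "")
                    ),
                    "exclusive_condition": (
                        f"{exclusive_cond[e][0]}:{exclusive_cond[e][1]}" if profiles[e] == "exclusive" else ""
                    ),
                }
                for c in CONDITIONS:
                    row[f"delta_{c[0]}_{c[1]}"] = deltas[c][e]
                truth_rows.append(row)
        records.append(
            SiteRecord(
                protein_ids=[protein],
                gene_name=gene,
                position=pos,
                residue=residue,
                localization_prob=float(loc_probs[ri]),
                reverse_flag=False,
                contaminant_flag=False,
                intensities=intensities,
                source_row=ri,
            )
        )

    # decoy / contaminant spike-ins
    n_decoy = rng.binomial(len(site_rows), config.decoy_rate)
    n_cont = rng.binomial(len(site_rows), config.contaminant_rate)
    for i in range(n_decoy + n_cont):
        is_decoy = i < n_decoy
        prefix = "REV__" if is_decoy else "CON__"
        intensities = {
            (sid, 1): float(2.0 ** rng.normal(config.baseline_mean, config.baseline_sd))
            for sid in rng.choice(sample_order, size=6, replace=False)
        }
        records.append(
            SiteRecord(
                protein_ids=[f"{prefix}X{i:04d}"],
                gene_name="",
                position=int(rng.integers(1, 500)),
                residue="S",
                localization_prob=float(rng.uniform(0.8, 1.0)),
                reverse_flag=is_decoy,
                contaminant_flag=not is_decoy,
                intensities=intensities,
                source_row=len(records),
            )
        )

    truth = pd.DataFrame(truth_rows).set_index(["protein", "position", "residue", "multiplicity"])

    # ---- protein-groups table ---------------------------------------------
    prot_reg = rng.random(config.n_proteins) < config.protein_regulated_fraction
    prot_trt = rng.choice(["bic", "ttx"], config.n_proteins)
    prot_delta = rng.uniform(config.effect_low, config.effect_high, config.n_proteins) * rng.choice(
        [-1.0, 1.0], config.n_proteins
    )
    prot_base = rng.normal(config.baseline_mean + 2.0, config.baseline_sd, config.n_proteins)
    prot_b = rng.normal(0.0, config.sigma_b, (config.n_proteins, config.n_bio))
    prot_eps = rng.normal(0.0, config.sigma_e, (config.n_proteins, n_samples))
    prot_log2 = np.empty((config.n_proteins, n_samples))
    for j, d in enumerate(design):
        col = prot_base + prot_b[:, d.bio_rep - 1] + prot_eps[:, j]
        active = prot_reg & (prot_trt == d.treatment)
        prot_log2[:, j] = col + np.where(active, prot_delta, 0.0)
    prot_missing = rng.random(prot_log2.shape) < config.mcar_rate

    prot_records: list[ProteinRecord] = []
    prot_truth_rows = []
    for i in range(config.n_proteins):
        lfq = {
            sid: float(2.0 ** prot_log2[i, j])
            for j, sid in enumerate(sample_order)
            if not prot_missing[i, j]
        }
        prot_records.append(
            ProteinRecord(
                protein_ids=[f"P{i + 1:05d}"],
                gene_name=f"Gene{i + 1}",
                unique_peptides=int(1 + rng.poisson(5)),
                reverse_flag=False,
                contaminant_flag=False,
                only_by_site_flag=False,
                lfq_intensities=lfq,
                source_row=i,
            )
        )
        prot_truth_rows.append(
            {
                "protein": f"P{i + 1:05d}",
                "regulated": bool(prot_reg[i]),
                "treatment": prot_trt[i] if prot_reg[i] else "",
                "delta": float(prot_delta[i]) if prot_reg[i] else 0.0,
            }
        )
    protein_truth = pd.DataFrame(prot_truth_rows).set_index("protein")

    # ---- write -------------------------------------------------------------
    sites_path = outdir / "phospho_sites.tsv"
    proteins_path = outdir / "protein_groups.tsv"
    design_path = outdir / "design.tsv"
    truth_path = outdir / "truth.tsv"
    protein_truth_path = outdir / "protein_truth.tsv"
    pio.write_phospho_sites(records, design, sites_path)
    pio.write_protein_groups(prot_records, design, proteins_path)
    pio.write_design(design, design_path)
    pio.write_table(truth.reset_index(), truth_path)
    pio.write_table(protein_truth.reset_index(), protein_truth_path)
    return SimResult(
        design=design,
        sites_path=sites_path,
        proteins_path=proteins_path,
        design_path=design_path,
        truth_path=truth_path,
        protein_truth_path=protein_truth_path,
        truth=truth,
        protein_truth=protein_truth,
    )


def simulate_pair_observations(
    n_events: int,
    delta,
    sigma_b: float = 0.25,
    sigma_e: float = 0.2,
    n_bio: int = 4,
    n_tech: int = 3,
    rng: np.random.Generator | None = None,
):
    """Direct draws from the mixed model for one treatment-control pair.

    ``delta`` is a scalar or per-event array of true treated-minus-control
    effects.  Yields the (y, arm, bio_rep) triple per event — the exact
    observation layout :func:`phoscale.diffreg.fit_random_intercept_ml`
    consumes.  Used for calibration and power studies without file I/O.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (n_events,))
    n_arm = n_bio * n_tech
    arm = np.array(["treated"] * n_arm + ["control"] * n_arm)
    bio = np.tile(np.repeat(np.arange(1, n_bio + 1), n_tech), 2)
    for e in range(n_events):
        b = rng.normal(0.0, sigma_b, n_bio)
        y = b[bio - 1] + rng.normal(0.0, sigma_e, 2 * n_arm)
        y[arm == "treated"] += delta[e]
        yield y, arm, bio


def simulate_kinase_substrate_table(
    truth: pd.DataFrame,
    n_kinases: int = 20,
    substrates_per_kinase: int = 10,
    planted_kinase: str | None = "kinase_planted",
    organism: str = "rat",
    rng: np.random.Generator | None = None,
) -> list[KinaseSubstrateRelation]:
    """A synthetic kinase-substrate table over the simulated sites.

    Random kinases get random substrate sites; the optional planted kinase
    gets substrates drawn from persistent/reciprocal events with positive
    bic effect, so its activity should rank first in a bic-condition KSEA.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sites = truth.reset_index()[["gene_name", "residue", "position", "profile", "delta_bic_24h"]]
    relations: list[KinaseSubstrateRelation] = []
    all_idx = np.arange(len(sites))
    for ki in range(n_kinases):
        chosen = rng.choice(all_idx, size=min(substrates_per_kinase, len(all_idx)), replace=False)
        for ci in chosen:
            row = sites.iloc[ci]
            relations.append(
                KinaseSubstrateRelation(
                    kinase_gene=f"kinase{ki + 1}",
                    substrate_gene=str(row["gene_name"]).casefold(),
                    residue=row["residue"],
                    position=int(row["position"]),
                    organism=organism,
                )
            )
    if planted_kinase:
        up = sites[(sites["profile"].isin(["persistent", "persistent_reciprocal"])) & (sites["delta_bic_24h"] > 0)]
        chosen = up.index.to_numpy()
        if len(chosen) > substrates_per_kinase:
            chosen = rng.choice(chosen, size=substrates_per_kinase, replace=False)
        for ci in chosen:
            row = sites.loc[ci]
            relations.append(
                KinaseSubstrateRelation(
                    kinase_gene=planted_kinase,
                    substrate_gene=str(row["gene_name"]).casefold(),
                    residue=row["residue"],
                    position=int(row["position"]),
                    organism=organism,
                )
            )
    return relations


def simulate_gene_sets(
    truth: pd.DataFrame,
    n_sets: int = 10,
    set_size: int = 25,
    rng: np.random.Generator | None = None,
) -> list[GeneSet]:
    """Random gene sets over the simulated genes, plus one set enriched in
    genes carrying regulated (non-null, non-exclusive) events."""
    if rng is None:
        rng = np.random.default_rng(0)
    genes = sorted({str(g).casefold() for g in truth["gene_name"]})
    sets = []
    for si in range(n_sets):
        members = rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        sets.append(GeneSet(term_id=f"SET:{si + 1:04d}", term_name=f"random set {si + 1}", members=frozenset(members)))
    reg = truth[~truth["profile"].isin(["null", "exclusive"])]
    reg_genes = sorted({str(g).casefold() for g in reg["gene_name"]})
    if reg_genes:
        members = rng.choice(reg_genes, size=min(set_size, len(reg_genes)), replace=False)
        sets.append(GeneSet(term_id="SET:REG", term_name="planted regulated set", members=frozenset(members)))
    return sets


# ---------------------------------------------------------------------------
# evaluation against truth
# ---------------------------------------------------------------------------


def evaluate_against_truth(
    diff_tables: dict[tuple[str, str], pd.DataFrame],
    calls: dict[str, pd.DataFrame],
    reciprocity: pd.DataFrame,
    truth: pd.DataFrame,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Returns per-condition sensitivity and empirical FDR, the
    temporal-class confusion matrix (per treatment, among detected
    events), and reciprocity precision/recall.
    """
    any_table = next(iter(diff_tables.values()))
    orphans = set(any_table.index) - set(truth.index)
    if orphans:
        raise ConfigError(f"events missing from truth: {sorted(orphans)[:5]}")

    metrics: dict = {"conditions": {}}
    for c, table in diff_tables.items():
        delta_col = f"delta_{c[0]}_{c[1]}"
        true_delta = truth[delta_col].reindex(table.index).fillna(0.0)
        tested = ~table["untestable"]
        is_true = (true_delta != 0) & tested
        called = table["regulated"].astype(bool)
        tp = int((called & is_true).sum())
        fp = int((called & ~is_true).sum())
        fn = int((~called & is_true).sum())
        metrics["conditions"]["%s_%s" % c] = {
            "n_tested": int(tested.sum()),
            "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
            "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
        }

    # temporal classification among detected events.  Two accuracies are
    # reported: over all detected events, and over events whose signature is
    # fully informed (no timepoint carries the "untested" annotation) — a
    # censored signature bit cannot be classified correctly by construction.
    confusion: dict[str, dict] = {}
    untested_cols = [f"untested_{tp}" for tp in pio.TIMEPOINTS]
    for trt, call_table in calls.items():
        conf: dict[tuple[str, str], int] = {}
        n_full = correct_full = 0
        planted = truth[
            (truth["treatment"].isin([trt, "both"]))
            & (~truth["profile"].isin(["null", "exclusive"]))
        ]
        for key, row in planted.iterrows():
            if key not in call_table.index:
                continue
            want = "persistent" if row["profile"] == "persistent_reciprocal" else row["profile"]
            got = call_table.loc[key, "temporal_class"]
            if got == "none":
                continue  # not detected
            conf[(want, got)] = conf.get((want, got), 0) + 1
            if not any(bool(call_table.loc[key, c]) for c in untested_cols):
                n_full += 1
                correct_full += got == want
        total = sum(conf.values())
        correct = sum(v for (w, g), v in conf.items() if w == g)
        confusion[trt] = {
            "n_detected": total,
            "accuracy": correct / total if total else float("nan"),
            "n_fully_tested": n_full,
            "accuracy_fully_tested": correct_full / n_full if n_full else float("nan"),
            "pairs": {f"{w}->{g}": v for (w, g), v in sorted(conf.items())},
        }
    metrics["temporal"] = confusion

    # reciprocity: planted reciprocal events testable under both treatments
    planted_rec = truth.index[truth["profile"] == "persistent_reciprocal"]
    testable = set(planted_rec)
    for table in diff_tables.values():
        testable &= set(table.index[~table["untestable"]])
    called_rec = set(reciprocity.loc[reciprocity["reciprocal"].astype(bool), "key"]) if len(reciprocity) else set()
    metrics["reciprocity"] = {
        "n_planted": int(len(planted_rec)),
        "n_planted_testable": len(testable),
        "recall": len(called_rec & testable) / len(testable) if testable else float("nan"),
        "precision": len(called_rec & set(planted_rec)) / len(called_rec) if called_rec else float("nan"),
    }
    return metrics


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["multiplicity_probs"] = list(d["multiplicity_probs"])
    return d
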