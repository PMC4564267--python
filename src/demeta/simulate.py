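"""Synthetic multi-study, multi-disease expression collections with known ground truth.

The generator emulates the study design the analysis assumes: six case/control
blood-transcriptomics datasets over four diseases (two rheumatoid-arthritis
and two lupus cohorts, one osteoarthritis, one ankylosing-spondylitis cohort)
on four array platforms, with partially overlapping gene panels, several
probes per gene, gene variances drawn from a scaled inverse-chi-square prior,
and differential-expression effects planted in configurable subsets of the
diseases.  Log-intensities are Gaussian:

    control sample:  x ~ N(b_g, sigma_g^2),   sigma_g^2 ~ s0^2 * d0 / chi2_{d0}
    affected case:   x ~ N(b_g + s_g * delta * sigma_g, sigma_g^2)

with per-gene sign s_g and effect delta in units of sigma_g.  Probe j of a
gene reports a_j + lambda_j * (x - b_g) + b_g + noise, so probes differ in
sensitivity and the largest-IQR collapse has real work to do.  Dead genes sit
at a low baseline with shrunken variance so the rank-sum filter is exercised;
planted markers are placed in the well-expressed, informative tier and on
every platform, so recovery experiments measure the detection statistics
rather than panel membership (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .io import (
    CASE,
    CONTROL,
    ExpressionDataset,
    StudyEntry,
    StudyManifest,
    write_manifest,
    write_probe_map,
)


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    disease: str
    platform: str
    n_case: int
    n_control: int


@dataclass(frozen=True)
class PlantedSet:
    """A group of genes differentially expressed in the given diseases."""

    n_genes: int
    diseases: tuple[str, ...]
    effect_size: float = 1.5  # in units of the gene's sigma
    sign_scheme: str = "shared"  # per-gene sign shared across diseases, or "mixed"


#: Default study layout: six datasets over four diseases with the deposited
#: cohort sizes (cases/controls): RA 18/15 and 20/11, SLE 11/6 and 21/45,
#: OA 106/33, AS 16/16; platforms shared as in the source collection.
DEFAULT_STUDIES = (
    StudySpec("RA1", "RA", "P1", 18, 15),
    StudySpec("RA2", "RA", "P2", 20, 11),
    StudySpec("SLE1", "SLE", "P3", 11, 6),
    StudySpec("SLE2", "SLE", "P3", 21, 45),
    StudySpec("OA", "OA", "P4", 106, 33),
    StudySpec("AS", "AS", "P4", 16, 16),
)

#: Default planted effects: a sizeable disease-specific signature per disease
#: and a small cross-disease core, mirroring the observed scale where each
#: study yields hundreds of DEGs but only a handful are shared by three or
#: more diseases.
DEFAULT_PLANTED = (
    PlantedSet(70, ("RA",)),
    PlantedSet(70, ("SLE",)),
    PlantedSet(70, ("OA",)),
    PlantedSet(70, ("AS",)),
    PlantedSet(20, ("RA", "SLE", "AS")),
    PlantedSet(6, ("RA", "SLE", "OA", "AS")),
)


@dataclass
class SimConfig:
    studies: tuple[StudySpec, ...] = DEFAULT_STUDIES
    n_genes: int = 8000
    probes_per_gene: tuple[tuple[int, ...], tuple[float, ...]] = (
        (1, 2, 3),
        (0.40, 0.35, 0.25),
    )
    platform_overlap: float = 0.90
    d0: float = 4.0
    s02: float = 0.05
    planted: tuple[PlantedSet, ...] = DEFAULT_PLANTED
    dead_gene_count: int = 800
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    dead_baseline_mean: float = 4.5
    dead_baseline_sd: float = 0.2
    dead_var_factor: float = 0.05
    # planted markers drawn above these quantiles of the baseline / variance-prior
    marker_baseline_quantile: float = 0.40
    marker_variance_quantile: float = 0.40
    probe_affinity_sd: float = 0.2
    probe_sensitivity_range: tuple[float, float] = (0.85, 1.0)
    probe_noise_sd: float = 0.05
    unannotated_probes_per_platform: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        planted_total = sum(ps.n_genes for ps in self.planted)
        if planted_total + self.dead_gene_count > self.n_genes:
            raise ValueError("planted + dead genes exceed n_genes")
        if not (0 < self.platform_overlap <= 1):
            raise ValueError("platform_overlap must lie in (0, 1]")
        known = {s.disease for s in self.studies}
        for ps in self.planted:
            unknown = set(ps.diseases) - known
            if unknown:
                raise ValueError(f"planted set names unknown disease(s): {sorted(unknown)}")
            if ps.effect_size < 0:
                raise ValueError("effect sizes must be non-negative")


@dataclass
class TruthRecord:
    """Planted-effect map: which genes affect which diseases, and the dead set."""

    table: pd.DataFrame  # gene-indexed: diseases, effect, sign, is_dead

    def planted_genes(self) -> set[str]:
        return set(self.table.index[self.table["diseases"] != ""])

    def dead_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_dead"]])

    def affected_diseases(self, gene: str) -> frozenset[str]:
        cell = self.table.loc[gene, "diseases"]
        return frozenset(cell.split(",")) if cell else frozenset()

    def common_genes(self, min_diseases: int = 3) -> set[str]:
        n = self.table["diseases"].str.count(",") + 1
        n[self.table["diseases"] == ""] = 0
        return set(self.table.index[n >= min_diseases])


@dataclass
class SimCollection:
    config: SimConfig
    datasets: dict[str, ExpressionDataset]  # probe-level, per study
    probe_maps: dict[str, pd.DataFrame]  # per platform
    truth: TruthRecord

    @property
    def study_to_disease(self) -> dict[str, str]:
        return {s.study_id: s.disease for s in self.config.studies}

    def probe_map_for(self, study_id: str) -> pd.DataFrame:
        spec = next(s for s in self.config.studies if s.study_id == study_id)
        return self.probe_maps[spec.platform]


def default_config(seed: int = 0, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed), **overrides)


def _truncated_normal_above(rng, quantile: float, size: int) -> np.ndarray:
    """Standard-normal draws conditioned above the given quantile."""
    u = rng.uniform(quantile, 1.0, size=size)
    return norm.ppf(u)


def generate_collection(config: SimConfig) -> SimCollection:
    """Draw a complete multi-study collection plus ground truth from one seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])

    # --- partition genes: dead / planted / background -----------------------
    perm = rng.permutation(n)
    dead_idx = perm[: config.dead_gene_count]
    cursor = config.dead_gene_count
    planted_idx: list[np.ndarray] = []
    for ps in config.planted:
        planted_idx.append(perm[cursor : cursor + ps.n_genes])
        cursor += ps.n_genes
    all_planted = np.concatenate(planted_idx) if planted_idx else np.array([], dtype=int)

    # --- gene-level parameters ---------------------------------------------
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)
    baseline[dead_idx] = (
        config.dead_baseline_mean
        + config.dead_baseline_sd * rng.standard_normal(len(dead_idx))
    )
    baseline[all_planted] = config.baseline_mean + config.baseline_sd * (
        _truncated_normal_above(rng, config.marker_baseline_quantile, len(all_planted))
    )

    sigma2 = config.s02 * config.d0 / rng.chisquare(config.d0, size=n)
    # markers: variance above the prior's q-quantile <=> chi-square draw below 1-q
    u = rng.uniform(1e-9, 1.0 - config.marker_variance_quantile, size=len(all_planted))
    sigma2[all_planted] = config.s02 * config.d0 / chi2.ppf(u, config.d0)
    sigma2[dead_idx] *= config.dead_var_factor
    sigma = np.sqrt(sigma2)

    # per-gene, per-disease effect in sigma units (signed)
    diseases = sorted({s.disease for s in config.studies})
    effect = {d: np.zeros(n) for d in diseases}
    sign = rng.choice([-1.0, 1.0], size=n)
    truth_diseases = np.array([""] * n, dtype=object)
    truth_effect = np.zeros(n)
    for ps, idx in zip(config.planted, planted_idx):
        for d in ps.diseases:
            if ps.sign_scheme == "shared":
                effect[d][idx] = sign[idx] * ps.effect_size
            else:
                effect[d][idx] = rng.choice([-1.0, 1.0], size=len(idx)) * ps.effect_size
        truth_diseases[idx] = ",".join(sorted(ps.diseases))
        truth_effect[idx] = ps.effect_size

    # --- platforms: panels and probes --------------------------------------
    platforms = sorted({s.platform for s in config.studies})
    anchor = np.zeros(n, dtype=bool)
    anchor[dead_idx] = True
    anchor[all_planted] = True
    panel_idx: dict[str, np.ndarray] = {}
    probe_tables: dict[str, pd.DataFrame] = {}
    probe_params: dict[str, dict[str, np.ndarray]] = {}
    sizes, probs = config.probes_per_gene
    for plat in platforms:
        on = anchor | (rng.uniform(size=n) < config.platform_overlap)
        idx = np.flatnonzero(on)
        panel_idx[plat] = idx
        counts = rng.choice(np.array(sizes), size=len(idx), p=np.array(probs))
        gene_of_probe = np.repeat(idx, counts)
        rep = np.concatenate([np.arange(c) for c in counts])
        probe_ids = np.array(
            [f"{plat}:{genes[g]}:{j + 1}" for g, j in zip(gene_of_probe, rep)]
        )
        lam = rng.uniform(*config.probe_sensitivity_range, size=len(probe_ids))
        aff = config.probe_affinity_sd * rng.standard_normal(len(probe_ids))
        # unannotated decoy probes: present on the array, empty gene symbol
        n_un = config.unannotated_probes_per_platform
        un_ids = np.array([f"{plat}:unann:{j + 1}" for j in range(n_un)])
        un_base = 6.0 + rng.standard_normal(n_un)
        probe_params[plat] = {
            "gene_idx": gene_of_probe,
            "lambda": lam,
            "affinity": aff,
            "un_base": un_base,
        }
        probe_tables[plat] = pd.DataFrame(
            {
                "probe_id": np.concatenate([probe_ids, un_ids]),
                "gene_symbol": np.concatenate(
                    [genes[gene_of_probe], np.array([""] * n_un)]
                ),
            }
        )

    # --- per-study sample matrices -----------------------------------------
    datasets: dict[str, ExpressionDataset] = {}
    for spec in config.studies:
        pp = probe_params[spec.platform]
        gidx = pp["gene_idx"]
        n_samp = spec.n_case + spec.n_control
        sample_ids = [f"{spec.study_id}_case{i + 1}" for i in range(spec.n_case)] + [
            f"{spec.study_id}_ctrl{i + 1}" for i in range(spec.n_control)
        ]
        panel = panel_idx[spec.platform]
        # gene-level signal for every panel gene
        signal = baseline[panel][:, None] + sigma[panel][:, None] * rng.standard_normal(
            (len(panel), n_samp)
        )
        shift = effect[spec.disease][panel] * sigma[panel]
        signal[:, : spec.n_case] += shift[:, None]
        rows = np.searchsorted(panel, gidx)  # panel indices are sorted
        centered = signal[rows] - baseline[gidx][:, None]
        probes = (
            baseline[gidx][:, None]
            + pp["lambda"][:, None] * centered
            + pp["affinity"][:, None]
            + config.probe_noise_sd * rng.standard_normal((len(gidx), n_samp))
        )
        un = pp["un_base"][:, None] + 0.3 * rng.standard_normal(
            (len(pp["un_base"]), n_samp)
        )
        values = pd.DataFrame(
            np.vstack([probes, un]),
            index=probe_tables[spec.platform]["probe_id"].to_numpy(),
            columns=sample_ids,
        )
        groups = pd.Series(
            [CASE] * spec.n_case + [CONTROL] * spec.n_control, index=sample_ids
        )
        datasets[spec.study_id] = ExpressionDataset(
            spec.study_id, spec.disease, values, groups
        )

    is_dead = np.zeros(n, dtype=bool)
    is_dead[dead_idx] = True
    truth = TruthRecord(
        pd.DataFrame(
            {
                "diseases": truth_diseases,
                "effect": truth_effect,
                "sign": sign,
                "is_dead": is_dead,
            },
            index=pd.Index(genes, name="gene"),
        )
    )
    return SimCollection(config, datasets, probe_tables, truth)


def write_collection(collection: SimCollection, out_dir: str | Path) -> StudyManifest:
    """Persist a collection as the TSV/manifest dialect the loaders read."""
    out = Path(out_dir)
    (out / "expr").mkdir(parents=True, exist_ok=True)
    (out / "probes").mkdir(exist_ok=True)
    entries = []
    for spec in collection.config.studies:
        ds = collection.datasets[spec.study_id]
        expr_path = out / "expr" / f"{spec.study_id}.tsv"
        ds.to_tsv(expr_path)
        ann_path = out / "probes" / f"{spec.platform}.tsv"
        entries.append(
            StudyEntry(
                study_id=spec.study_id,
                disease=spec.disease,
                expression_path=expr_path,
                annotation_path=ann_path,
                case_ids=ds.case_ids,
                control_ids=ds.control_ids,
            )
        )
    for plat, table in collection.probe_maps.items():
        write_probe_map(table, out / "probes" / f"{plat}.tsv")
    truth_out = collection.truth.table.copy()
    truth_out.to_csv(out / "truth.tsv", sep="\t")
    manifest = StudyManifest(entries)
    write_manifest(manifest, out / "manifest.yaml")
    return manifest
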