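"""Simulation of GWAS summary statistics with realistic cis-region structure.

The generator emulates the statistical structure of the study inputs —
cis regions of LD-correlated variants for each protein, a standardized
quantitative outcome, per-SNP standard errors 1/sqrt(2 n f (1-f)) — so the
whole pipeline can be exercised end-to-end with known ground truth.

Marginal association z-scores in a region follow the standard
summary-statistic model: if z_joint holds the joint (causal) z-scores,
the marginal z is multivariate normal with mean R z_joint and covariance
R, where R is the LD correlation matrix.  Scenarios cover a null protein
(cis signal, no outcome effect), a shared causal variant with effect
theta on the outcome, a linkage pair of distinct causal variants, reverse
causation, a mediation chain and sex-specific effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .summary_stats import (LDMatrix, RegionDataset, VariantAssociation,
                            PVAL_FLOOR, write_ld_matrix, write_summary_table,
                            zscore_pval)

SCENARIOS = ("null", "shared_causal", "linkage", "reverse",
             "mediation_chain", "sex_specific")

#: Non-palindromic allele pairs cycled across simulated variants.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated cis region's data-generating conditions.

    Sample-size defaults mirror the study setting: protein GWAS of about
    33,000 effective samples and a heel-BMD outcome GWAS of 426,824.
    The exposure carries one causal cis variant of effect 0.15 SD per
    allele unless configured otherwise.
    """

    scenario: str = "shared_causal"
    m_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.8
    causal_indices: tuple[int, ...] = (25,)
    exposure_effects: tuple[float, ...] = (0.15,)
    theta: float = 0.3
    theta_female: float | None = None
    theta_male: float | None = None
    linkage_indices: tuple[int, ...] | None = None
    linkage_effects: tuple[float, ...] | None = None
    mediation_a: float = 0.02      # exposure -> mediator
    mediation_b: float = 0.1       # mediator -> outcome
    mediation_direct: float = 0.03  # residual direct path
    n_exposure: int = 33_000
    n_outcome: int = 426_824
    n_mediator: int = 461_460
    chrom: str = "1"
    gene_start: int = 50_000_000
    gene_end: int = 50_010_000
    snp_span_bp: int = 1_000_000
    snp_prefix: str = "rs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(i >= self.m_snps for i in self.causal_indices):
            raise ValueError("causal index beyond m_snps")
        if min(self.n_exposure, self.n_outcome) <= 10:
            raise ValueError("n must exceed 10")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")


def make_ld(m_snps: int, rho: float,
            snp_ids: Sequence[str] | None = None) -> LDMatrix:
    """AR(1) LD correlation matrix: r[i, j] = rho^|i-j| (PSD by construction)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if snp_ids is None:
        snp_ids = tuple(f"rs{i + 1}" for i in range(m_snps))
    if len(snp_ids) != m_snps:
        raise ValueError("snp_ids length must equal m_snps")
    idx = np.arange(m_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :]) if rho > 0 \
        else np.eye(m_snps)
    return LDMatrix(tuple(snp_ids), np.asarray(r, dtype=float))


def _chol(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(r + 1e-10 * np.eye(len(r)))


def _joint_effects(m: int, indices: Sequence[int],
                   effects: Sequence[float]) -> np.ndarray:
    beta = np.zeros(m)
    for i, b in zip(indices, effects):
        beta[i] = b
    return beta


def _draw_trait(rng: np.random.Generator, ld: LDMatrix, chol: np.ndarray,
                mafs: np.ndarray, positions: np.ndarray,
                joint_beta: np.ndarray, n: float, trait_id: str,
                trait_kind: str, spec: ScenarioSpec,
                with_gene: bool = True,
                attach_ld: bool = False) -> RegionDataset:
    m = len(mafs)
    se = 1.0 / np.sqrt(2.0 * n * mafs * (1.0 - mafs))
    z_joint = joint_beta / se
    z = ld.r @ z_joint + chol @ rng.standard_normal(m)
    beta = z * se
    pvals = np.maximum(2.0 * _norm_sf(np.abs(z)), PVAL_FLOOR)
    records = []
    for j in range(m):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        records.append(VariantAssociation(
            snp_id=ld.snp_ids[j], chrom=spec.chrom, pos=int(positions[j]),
            effect_allele=ea, other_allele=oa, eaf=float(mafs[j]),
            beta=float(beta[j]), se=float(se[j]), pval=float(pvals[j]),
            n=float(n)))
    return RegionDataset(
        trait_id=trait_id, trait_kind=trait_kind,
        gene_chrom=spec.chrom if with_gene else None,
        gene_start=spec.gene_start if with_gene else None,
        gene_end=spec.gene_end if with_gene else None,
        records=records, ld=ld if attach_ld else None)


def _norm_sf(x: np.ndarray) -> np.ndarray:
    from scipy import stats
    return stats.norm.sf(x)


def simulate_region(spec: ScenarioSpec,
                    trait_ids: Mapping[str, str] | None = None,
                    ) -> dict[str, RegionDataset]:
    """Simulate one cis region for all traits the scenario involves.

    Returns a dict keyed by role — always ``exposure`` and ``outcome``;
    ``mediator`` for the mediation chain; ``outcome_female`` and
    ``outcome_male`` for the sex-specific scenario.  Deterministic given
    ``spec.seed``; each trait consumes an independent child stream, so
    adding a trait never perturbs another's draw.
    """
    ids = dict(trait_ids or {})
    m = spec.m_snps
    ss = np.random.SeedSequence(spec.seed)
    # fixed fan-out: child 0 for region features, 1.. for traits in role order
    children = ss.spawn(8)
    rng_region = np.random.default_rng(children[0])

    mafs = rng_region.uniform(*spec.maf_range, size=m)
    start = spec.gene_start - spec.snp_span_bp // 2
    positions = start + np.round(np.linspace(
        0, spec.snp_span_bp + (spec.gene_end - spec.gene_start), m)
    ).astype(int)
    snp_ids = tuple(f"{spec.snp_prefix}{j + 1}" for j in range(m))
    ld = make_ld(m, spec.ld_rho, snp_ids)
    chol = _chol(ld.r)

    beta_x = _joint_effects(m, spec.causal_indices, spec.exposure_effects)

    def draw(child_i: int, joint: np.ndarray, n: float, tid: str,
             kind: str, with_gene: bool = True,
             attach_ld: bool = True) -> RegionDataset:
        return _draw_trait(np.random.default_rng(children[child_i]), ld,
                           chol, mafs, positions, joint, n, tid, kind, spec,
                           with_gene, attach_ld)

    out: dict[str, RegionDataset] = {}
    sc = spec.scenario
    if sc == "reverse":
        # outcome trait is causal for the protein: the region's signal
        # originates in the outcome and leaks into the protein scaled by theta
        beta_y = _joint_effects(m, spec.causal_indices,
                                spec.exposure_effects)
        beta_x = spec.theta * beta_y
        out["exposure"] = draw(1, beta_x, spec.n_exposure,
                               ids.get("exposure", "PROT"), "protein")
        out["outcome"] = draw(2, beta_y, spec.n_outcome,
                              ids.get("outcome", "OUTCOME"), "outcome",
                              with_gene=False)
        return out

    out["exposure"] = draw(1, beta_x, spec.n_exposure,
                           ids.get("exposure", "PROT"), "protein",
                           attach_ld=True)
    if sc == "null":
        beta_y = np.zeros(m)
    elif sc == "shared_causal":
        beta_y = spec.theta * beta_x
    elif sc == "linkage":
        li = spec.linkage_indices
        if li is None:
            # default: outcome causal variant 5 SNPs away from the first
            # exposure causal variant (r ~ rho^5 under AR(1))
            li = (min(spec.causal_indices[0] + 5, m - 1),)
        le = spec.linkage_effects or tuple(
            spec.theta * b for b in spec.exposure_effects[:len(li)])
        beta_y = _joint_effects(m, li, le)
    elif sc == "mediation_chain":
        a, b, c = spec.mediation_a, spec.mediation_b, spec.mediation_direct
        beta_med = a * beta_x
        beta_y = (a * b + c) * beta_x
        out["mediator"] = draw(3, beta_med, spec.n_mediator,
                               ids.get("mediator", "MEDIATOR"), "mediator",
                               with_gene=False)
    elif sc == "sex_specific":
        tf = spec.theta_female if spec.theta_female is not None else spec.theta
        tm = spec.theta_male if spec.theta_male is not None else 0.0
        beta_y = 0.5 * (tf + tm) * beta_x
        out["outcome_female"] = draw(4, tf * beta_x, spec.n_outcome // 2,
                                     ids.get("outcome_female", "OUTCOME_F"),
                                     "outcome", with_gene=False)
        out["outcome_male"] = draw(5, tm * beta_x, spec.n_outcome // 2,
                                   ids.get("outcome_male", "OUTCOME_M"),
                                   "outcome", with_gene=False)
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(sc)
    out["outcome"] = draw(2, beta_y, spec.n_outcome,
                          ids.get("outcome", "OUTCOME"), "outcome",
                          with_gene=False)
    return out


# ---------------------------------------------------------------------------
# Whole-study bundles
# ---------------------------------------------------------------------------

@dataclass
class SimulatedProtein:
    """One protein's region across all traits, with its ground truth."""

    protein_id: str
    scenario: str
    theta: float
    regions: dict[str, RegionDataset]
    ld: LDMatrix

    @property
    def exposure(self) -> RegionDataset:
        return self.regions["exposure"]

    @property
    def outcome(self) -> RegionDataset:
        return self.regions["outcome"]


@dataclass
class StudyBundle:
    """A self-consistent set of simulated study inputs plus ground truth."""

    proteins: list[SimulatedProtein]
    #: the mediator's own cis region against the outcome (mediation step 2)
    mediator_region: SimulatedProtein | None
    manifest: dict

    def protein(self, protein_id: str) -> SimulatedProtein:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def simulate_study(protein_count: int,
                   spec_defaults: ScenarioSpec | None = None,
                   seed: int = 0,
                   scenarios: Sequence[str] | None = None,
                   n_causal: int | None = None,
                   out_dir: str | Path | None = None) -> StudyBundle:
    """Simulate a whole study: many protein cis regions plus shared traits.

    By default the first ``n_causal`` proteins (one fifth, at least one)
    follow the shared-causal scenario with effect ``spec_defaults.theta``
    and the rest are null.  An explicit ``scenarios`` sequence (one tag
    per protein) overrides this.  A ground-truth manifest travels with the
    bundle; with ``out_dir`` the bundle is also written as TSV files plus
    a YAML manifest consumable by the command-line pipeline.
    """
    if protein_count < 1:
        raise ValueError("protein_count must be at least 1")
    base = spec_defaults or ScenarioSpec()
    if scenarios is None:
        if n_causal is None:
            n_causal = max(1, protein_count // 5)
        scenarios = tuple("shared_causal" if i < n_causal else "null"
                          for i in range(protein_count))
    if len(scenarios) != protein_count:
        raise ValueError("scenarios length must equal protein_count")

    proteins: list[SimulatedProtein] = []
    need_mediator = any(s == "mediation_chain" for s in scenarios)
    for i, sc in enumerate(scenarios):
        pid = f"PROT{i + 1:03d}"
        pseed = int(_child_seed(seed, i).generate_state(1)[0] % (2 ** 31))
        chrom = str(1 + (i % 22))
        gene_start = 50_000_000 + (i // 22) * 5_000_000
        spec = replace(base, scenario=sc, seed=pseed, chrom=chrom,
                       gene_start=gene_start,
                       gene_end=gene_start + (base.gene_end - base.gene_start),
                       snp_prefix=f"rs{i + 1}_")
        regions = simulate_region(spec, trait_ids={"exposure": pid})
        theta = {"null": 0.0, "linkage": 0.0, "reverse": 0.0}.get(
            sc, spec.theta)
        if sc == "mediation_chain":
            theta = spec.mediation_a * spec.mediation_b + spec.mediation_direct
        proteins.append(SimulatedProtein(
            protein_id=pid, scenario=sc, theta=theta, regions=regions,
            ld=regions["exposure"].ld))

    mediator_region = None
    if need_mediator:
        mseed = int(_child_seed(seed, 10_000).generate_state(1)[0]
                    % (2 ** 31))
        mspec = replace(base, scenario="shared_causal", seed=mseed,
                        theta=base.mediation_b, chrom="22",
                        gene_start=100_000_000, gene_end=100_010_000,
                        snp_prefix="rsM_", n_exposure=base.n_mediator)
        regions = simulate_region(mspec, trait_ids={"exposure": "MEDIATOR"})
        regions["exposure"].trait_kind = "mediator"
        mediator_region = SimulatedProtein(
            protein_id="MEDIATOR", scenario="shared_causal",
            theta=base.mediation_b, regions=regions,
            ld=regions["exposure"].ld)

    manifest = {
        "seed": seed,
        "proteins": [{"protein_id": p.protein_id, "scenario": p.scenario,
                      "true_theta": float(p.theta),
                      "gene_chrom": p.exposure.gene_chrom,
                      "gene_start": p.exposure.gene_start,
                      "gene_end": p.exposure.gene_end}
                     for p in proteins],
    }
    bundle = StudyBundle(proteins=proteins, mediator_region=mediator_region,
                         manifest=manifest)
    if out_dir is not None:
        write_study(bundle, out_dir)
    return bundle


def _region_files(p: SimulatedProtein) -> dict[str, str]:
    files = {"exposure": f"{p.protein_id}_exposure.tsv",
             "outcome": f"{p.protein_id}_outcome.tsv",
             "ld": f"{p.protein_id}_ld.tsv"}
    for extra in ("mediator", "outcome_female", "outcome_male"):
        if extra in p.regions:
            files[extra] = f"{p.protein_id}_{extra}.tsv"
    return files


def write_study(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Write a bundle as TSVs plus a YAML manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    items = list(bundle.proteins)
    if bundle.mediator_region is not None:
        items.append(bundle.mediator_region)
    for p in items:
        files = _region_files(p)
        for role, fname in files.items():
            if role == "ld":
                write_ld_matrix(p.ld, out / fname)
            else:
                write_summary_table(p.regions[role], out / fname)
        entries.append({
            "protein_id": p.protein_id, "scenario": p.scenario,
            "true_theta": float(p.theta),
            "gene_chrom": p.exposure.gene_chrom,
            "gene_start": p.exposure.gene_start,
            "gene_end": p.exposure.gene_end,
            "is_mediator_region": p is bundle.mediator_region,
            "files": files,
        })
    manifest = dict(bundle.manifest)
    manifest["entries"] = entries
    path = out / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_study(manifest_path: str | Path) -> StudyBundle:
    """Reconstruct a StudyBundle from a written study directory."""
    from .summary_stats import read_ld_matrix, read_summary_table

    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    proteins: list[SimulatedProtein] = []
    mediator_region = None
    for e in manifest.get("entries", []):
        regions: dict[str, RegionDataset] = {}
        ld = read_ld_matrix(base / e["files"]["ld"])
        for role, fname in e["files"].items():
            if role == "ld":
                continue
            kind = ("protein" if role == "exposure" else
                    "mediator" if role == "mediator" else "outcome")
            gene = role == "exposure"
            regions[role] = read_summary_table(
                base / fname,
                trait_id=e["protein_id"] if role == "exposure" else
                f"{e['protein_id']}:{role}",
                trait_kind=kind,
                gene_chrom=e["gene_chrom"] if gene else None,
                gene_start=e["gene_start"] if gene else None,
                gene_end=e["gene_end"] if gene else None)
        for reg in regions.values():
            reg.ld = ld
        sp = SimulatedProtein(protein_id=e["protein_id"],
                              scenario=e["scenario"],
                              theta=float(e["true_theta"]),
                              regions=regions, ld=ld)
        if e.get("is_mediator_region"):
            mediator_region = sp
            sp.regions["exposure"].trait_kind = "mediator"
        else:
            proteins.append(sp)
    return StudyBundle(proteins=proteins, mediator_region=mediator_region,
                       manifest={k: v for k, v in manifest.items()
                                 if k != "entries"})
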