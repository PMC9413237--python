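"""Synthetic population-based cytotoxicity screen generator.

Emulates a plate-based lymphoblastoid-cell-line screen: a panel of donor
cell lines with lognormally varying Hill concentration-response parameters,
384-well plates with vehicle (0.5% DMSO) and positive-control (100 uM
tetra-octyl ammonium bromide, TAB) wells and five 10x serial dilutions run
on replicate plates, genotype matrices with optional planted causal
variants, and defined-mixture recipes.

Every generator is deterministic given its seed, so downstream stages
(normalization/QC, hierarchical Bayesian fitting, POD/TDVF derivation,
association mapping) are testable end-to-end without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hill import hill_response

__all__ = [
    "PopulationSpec",
    "PlateLayoutSpec",
    "GenotypeSimSpec",
    "GenotypeMatrix",
    "simulate_population",
    "simulate_plates",
    "simulate_genotypes",
    "build_mixture_recipe",
    "write_plates",
    "read_plates",
    "write_genotype_tsv",
    "write_vcf",
    "read_genotype_tsv",
    "write_sample_metadata",
]

#: Five 10x serial dilutions used by the screen design, in uM.
DEFAULT_CONCENTRATIONS = (0.01, 0.1, 1.0, 10.0, 100.0)


class SpecValidationError(ValueError):
    """A simulation spec field violates its invariant."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PopulationSpec:
    """Population distribution of individual Hill parameters.

    Individual parameters are normal on transformed scales: ln EC50 and
    ln y0 are normal, and the Hill coefficient is n = 1 + exp(z) with z
    normal, which keeps n >= 1 with smooth support.

    Defaults describe a moderately potent, moderately variable substance:
    EC50 centred at 10 uM (the middle of the 0.01-100 uM tested decade
    span) with ln-scale SD 0.5, baseline y0 ~ 1 with 5% spread, median
    Hill coefficient 2, and additive response noise with scale 0.1
    (10% of the vehicle level) and Student-t tails (nu = 5).
    """

    n_individuals: int = 146
    mu_log_ec50: float = math.log(10.0)
    sd_log_ec50: float = 0.5
    mu_log_y0: float = 0.0
    sd_log_y0: float = 0.05
    mu_log_nshift: float = 0.0
    sd_log_nshift: float = 0.5
    error_scale: float = 0.1
    error_df: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_individuals >= 2, "n_individuals", "must be >= 2")
        for name in ("sd_log_ec50", "sd_log_y0", "sd_log_nshift"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.error_scale >= 0, "error_scale", "must be >= 0")
        _require(self.error_df > 0, "error_df", "must be > 0")


@dataclass(frozen=True)
class PlateLayoutSpec:
    """Layout of one 384-well screening plate (per cell line, per substance).

    Vehicle wells define the normalization baseline; positive-control wells
    (complete kill) anchor the QC gate.  Well counts per plate follow the
    screen's control blocks and are configurable.
    """

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_replicate_plates: int = 3
    n_vehicle_wells: int = 16
    n_positive_wells: int = 8
    vehicle_luminescence_mean: float = 1.0e6
    vehicle_luminescence_cv: float = 0.10

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        _require(conc.size >= 1, "concentrations", "must be non-empty")
        _require(bool(np.all(conc > 0)), "concentrations", "must be positive")
        _require(bool(np.all(np.diff(conc) > 0)), "concentrations",
                 "must be strictly increasing")
        for name in ("n_replicate_plates", "n_vehicle_wells", "n_positive_wells"):
            _require(getattr(self, name) >= 1, name, "must be >= 1")
        _require(self.vehicle_luminescence_mean > 0,
                 "vehicle_luminescence_mean", "must be > 0")
        _require(self.vehicle_luminescence_cv >= 0,
                 "vehicle_luminescence_cv", "must be >= 0")


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Genotype panel simulation: SNP count, allele-frequency range,
    ancestry structure, and optional causal variants.

    ``causal_snps`` maps SNP index -> additive effect (beta) on ln EC50 per
    copy of the minor allele.  ``group_divergence`` is a Balding-Nichols
    Fst-like drift parameter: per-group allele frequencies are drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p.
    """

    n_snps: int = 2000
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    causal_snps: tuple[tuple[int, float], ...] = ()
    n_ancestry_groups: int = 1
    group_divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_snps >= 1, "n_snps", "must be >= 1")
        lo, hi = self.maf_bounds
        _require(0 < lo <= hi <= 0.5, "maf_bounds", "must satisfy 0 < lo <= hi <= 0.5")
        for idx, _beta in self.causal_snps:
            _require(0 <= idx < self.n_snps, "causal_snps",
                     f"index {idx} out of range for n_snps={self.n_snps}")
        _require(self.n_ancestry_groups >= 1, "n_ancestry_groups", "must be >= 1")
        _require(0 <= self.group_divergence < 1, "group_divergence",
                 "must be in [0, 1)")


@dataclass
class GenotypeMatrix:
    """Minor-allele count matrix (samples x SNPs) with annotations.

    ``genotypes``: DataFrame of 0/1/2 counts, index = sample ids, columns =
    SNP ids.  ``snps``: per-SNP table (snp_id, chrom, pos, maf).
    ``samples``: per-sample table (sample_id, sex, ancestry_group).
    """

    genotypes: pd.DataFrame
    snps: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def simulate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw per-individual true Hill parameters for a donor population.

    Returns a DataFrame indexed by ``cell_line_id`` with columns ``y0``,
    ``ec50`` (uM), ``n`` (Hill coefficient, always >= 1) and ``sex``
    (alternating F/M: the panel is balanced by design).
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_individuals
    ln_y0 = rng.normal(spec.mu_log_y0, spec.sd_log_y0, k)
    ln_ec50 = rng.normal(spec.mu_log_ec50, spec.sd_log_ec50, k)
    z = rng.normal(spec.mu_log_nshift, spec.sd_log_nshift, k)
    ids = [f"ind{i:04d}" for i in range(k)]
    return pd.DataFrame(
        {
            "y0": np.exp(ln_y0),
            "ec50": np.exp(ln_ec50),
            "n": 1.0 + np.exp(z),
            "sex": ["F" if i % 2 == 0 else "M" for i in range(k)],
        },
        index=pd.Index(ids, name="cell_line_id"),
    )


def simulate_plates(
    individual_params: pd.DataFrame,
    layout: PlateLayoutSpec = PlateLayoutSpec(),
    error_scale: float = 0.1,
    error_df: float = 5.0,
    seed: int = 0,
    chemical_id: str = "chem01",
) -> pd.DataFrame:
    """Simulate raw luminescence plates for one test substance.

    Each (cell line, replicate plate) gets vehicle wells fluctuating with
    the stated CV, positive-control wells with a trace residual signal,
    and one treatment well per concentration.  The latent treatment
    response is the downward Hill curve plus additive scaled Student-t
    noise on the response-fraction scale; raw counts are that response
    times the plate's realized vehicle mean, floored at zero (luminescence
    cannot be negative).  Normalizing by the same-plate vehicle mean
    therefore recovers response = hill + noise exactly, and with
    ``error_scale=0`` the normalized response equals the Hill curve
    analytically.

    Returns a PlateSet DataFrame with columns: plate_id, cell_line_id,
    population_label, sex, well_role, chemical_id, concentration_uM,
    raw_luminescence.
    """
    if layout.vehicle_luminescence_mean <= 0:
        raise SpecValidationError("vehicle_luminescence_mean: must be > 0")
    if error_df <= 0:
        raise SpecValidationError("error_df: must be > 0")
    rng = np.random.default_rng(seed)
    conc = np.asarray(layout.concentrations, dtype=float)
    rows: list[dict] = []
    vm = layout.vehicle_luminescence_mean
    cv = layout.vehicle_luminescence_cv
    for cid, p in individual_params.iterrows():
        sex = p.get("sex", "U")
        pop = p.get("population_label", "pop1")
        curve = hill_response(p["y0"], p["ec50"], p["n"], conc)
        for rep in range(1, layout.n_replicate_plates + 1):
            plate_id = f"{cid}_{chemical_id}_p{rep}"
            veh = vm * (1.0 + cv * rng.standard_normal(layout.n_vehicle_wells))
            veh = np.maximum(veh, 0.0)
            veh_mean = veh.mean()
            if veh_mean <= 0:
                raise SpecValidationError(
                    "vehicle wells: realized plate vehicle mean is non-positive")
            # positive controls: complete kill leaves only a trace residual
            pos = veh_mean * np.abs(
                0.002 * (1.0 + 0.5 * rng.standard_normal(layout.n_positive_wells)))
            noise = error_scale * rng.standard_t(error_df, conc.size)
            treat = veh_mean * np.maximum(curve + noise, 0.0)
            for v in veh:
                rows.append(dict(plate_id=plate_id, cell_line_id=cid,
                                 population_label=pop, sex=sex,
                                 well_role="vehicle", chemical_id=chemical_id,
                                 concentration_uM=0.0, raw_luminescence=v))
            for v in pos:
                rows.append(dict(plate_id=plate_id, cell_line_id=cid,
                                 population_label=pop, sex=sex,
                                 well_role="positive", chemical_id="TAB",
                                 concentration_uM=100.0, raw_luminescence=v))
            for x, v in zip(conc, treat):
                rows.append(dict(plate_id=plate_id, cell_line_id=cid,
                                 population_label=pop, sex=sex,
                                 well_role="treatment", chemical_id=chemical_id,
                                 concentration_uM=x, raw_luminescence=v))
    return pd.DataFrame(rows)


def simulate_genotypes(
    gspec: GenotypeSimSpec,
    individual_params: pd.DataFrame,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate Hardy-Weinberg genotypes and apply causal effects.

    Samples ancestral allele frequencies uniformly within ``maf_bounds``;
    with more than one ancestry group and nonzero divergence, per-group
    frequencies drift around the ancestral value (Balding-Nichols Beta
    model).  Individuals are assigned to groups in contiguous blocks of
    near-equal size.  Causal SNPs shift each carrier's ln EC50 by
    beta x allele count; the returned parameter table has ``ec50``
    updated accordingly (other columns untouched).

    Returns ``(GenotypeMatrix, adjusted_params)``.
    """
    rng = np.random.default_rng(gspec.seed)
    n = len(individual_params)
    m = gspec.n_snps
    lo, hi = gspec.maf_bounds
    p_anc = rng.uniform(lo, hi, m)

    groups = np.array_split(np.arange(n), gspec.n_ancestry_groups)
    geno = np.empty((n, m), dtype=np.int8)
    group_labels = np.empty(n, dtype=object)
    for g, idx in enumerate(groups):
        if gspec.n_ancestry_groups > 1 and gspec.group_divergence > 0:
            f = gspec.group_divergence
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_g = rng.beta(a, b)
        else:
            p_g = p_anc
        geno[idx, :] = rng.binomial(2, p_g, size=(idx.size, m)).astype(np.int8)
        group_labels[idx] = f"group{g + 1}"

    for snp_idx, beta in gspec.causal_snps:
        if geno[:, snp_idx].min() == geno[:, snp_idx].max():
            raise SpecValidationError(
                f"causal_snps: SNP {snp_idx} is monomorphic in the sample; "
                "a causal effect on it is unidentifiable")

    snp_ids = [f"snp{i:06d}" for i in range(m)]
    # synthetic map: SNPs spread over 22 autosomes at 10 kb spacing
    chroms = (np.arange(m) % 22) + 1
    pos = (np.arange(m) // 22 + 1) * 10_000
    freq = geno.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    gm = GenotypeMatrix(
        genotypes=pd.DataFrame(geno, index=individual_params.index.copy(),
                               columns=snp_ids),
        snps=pd.DataFrame({"snp_id": snp_ids, "chrom": chroms,
                           "pos": pos, "maf": maf}).set_index("snp_id"),
        samples=pd.DataFrame({
            "sample_id": individual_params.index,
            "sex": individual_params.get(
                "sex", pd.Series("U", index=individual_params.index)).values,
            "ancestry_group": group_labels,
        }).set_index("sample_id"),
    )

    adjusted = individual_params.copy()
    if gspec.causal_snps:
        shift = np.zeros(n)
        for snp_idx, beta in gspec.causal_snps:
            shift += beta * geno[:, snp_idx]
        adjusted["ec50"] = np.exp(np.log(adjusted["ec50"].to_numpy()) + shift)
    return gm, adjusted


def build_mixture_recipe(
    reference_values: dict[str, float],
    scenario: str,
    level: str,
) -> pd.DataFrame:
    """Build a defined-mixture recipe from per-chemical reference values.

    Each chemical's mass fraction of the mixture stock is proportional to
    its reference value for the chosen scenario (POD, RfD, Exposure or
    AC50) at the chosen level ("low" = population median, "high" = upper
    95th percentile), mirroring how exposure- or hazard-based defined
    mixtures are assembled.
    """
    if scenario not in {"POD", "RfD", "Exposure", "AC50"}:
        raise SpecValidationError(
            f"scenario: {scenario!r} not one of POD/RfD/Exposure/AC50")
    if level not in {"low", "high"}:
        raise SpecValidationError(f"level: {level!r} not one of low/high")
    if not reference_values:
        raise SpecValidationError("reference_values: must be non-empty")
    chems = list(reference_values)
    vals = np.asarray([reference_values[c] for c in chems], dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        bad = [c for c, v in zip(chems, vals) if not (v > 0 and np.isfinite(v))]
        raise SpecValidationError(
            f"reference_values: non-positive or non-finite for {bad}")
    frac = vals / vals.sum()
    return pd.DataFrame({
        "chemical_id": chems,
        "scenario": scenario,
        "level": level,
        "reference_value": vals,
        "mass_fraction": frac,
    })


# ---------------------------------------------------------------------------
# I/O: plain-text interchange formats

PLATE_COLUMNS = ["plate_id", "cell_line_id", "population_label", "sex",
                 "well_role", "chemical_id", "concentration_uM",
                 "raw_luminescence"]


def write_plates(plates: pd.DataFrame, path) -> None:
    plates.to_csv(path, index=False, columns=PLATE_COLUMNS)


def read_plates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return df


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Samples x SNPs matrix of 0/1/2 counts, tab-separated."""
    gm.genotypes.to_csv(path, sep="\t", index_label="sample_id")


def read_genotype_tsv(path, sample_metadata=None, snp_table=None) -> GenotypeMatrix:
    geno = pd.read_csv(path, sep="\t", index_col="sample_id")
    if snp_table is not None:
        snps = pd.read_csv(snp_table, sep="\t").set_index("snp_id")
    else:
        freq = geno.mean(axis=0) / 2.0
        snps = pd.DataFrame({
            "snp_id": geno.columns,
            "chrom": (np.arange(geno.shape[1]) % 22) + 1,
            "pos": (np.arange(geno.shape[1]) // 22 + 1) * 10_000,
            "maf": np.minimum(freq, 1 - freq).to_numpy(),
        }).set_index("snp_id")
    if sample_metadata is not None:
        samples = pd.read_csv(sample_metadata, sep="\t").set_index("sample_id")
    else:
        samples = pd.DataFrame({"sample_id": geno.index, "sex": "U",
                                "ancestry_group": "group1"}).set_index("sample_id")
    return GenotypeMatrix(genotypes=geno, snps=snps, samples=samples.loc[geno.index])


def write_sample_metadata(gm: GenotypeMatrix, path) -> None:
    gm.samples.to_csv(path, sep="\t", index_label="sample_id")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields only (A/C placeholder alleles)."""
    samples = list(gm.genotypes.index)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        geno = gm.genotypes.to_numpy()
        for j, snp_id in enumerate(gm.genotypes.columns):
            info = gm.snps.loc[snp_id]
            gts = "\t".join(gt_codes[int(g)] for g in geno[:, j])
            fh.write(f"{int(info['chrom'])}\t{int(info['pos'])}\t{snp_id}"
                     f"\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def write_mixture_recipe(recipe: pd.DataFrame, path) -> None:
    recipe.to_csv(path, sep="\t", index=False)
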