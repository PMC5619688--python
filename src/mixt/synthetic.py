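"""Synthetic matched two-tissue cohorts with planted ground truth.

The generator realizes the latent-factor view of a co-expression module:
every module m of tissue t has one standard-normal factor per sample, and a
member gene g measures that factor with a loading,

    x_g = s_g * lambda * f_{m,t,sample} + eps,   eps ~ N(0, noise_sd),

with sign s_g in {+1,-1} (a configured fraction of members load
negatively) and lambda = sqrt(c/(1-c)) * noise_sd chosen in closed form so
the expected within-module gene-gene |correlation| is the target c.  Genes
not in any module are pure noise.  A planted cross-tissue interaction makes
the tumor-module and blood-module factors bivariate-normal with correlation
rho for the patients of one subtype stratum and independent elsewhere;
blood-only controls draw factors from the baseline distribution.  Subtype
labels and categorical attributes are sampled independently of the factors
(so null calibration is exact by construction); continuous attributes may
be linked to a module factor.

Within each tissue, genes are assigned to modules by an independent random
permutation of a gene namespace shared between the tissues, so the
gene-composition overlap of any tumor/blood module pair is hypergeometric
by construction.

Everything is driven by one seed: regenerating from the same config is
bit-identical, and the emitted truth (memberships, factors, realized
interaction correlations) is what recovery tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .data_io import ClinicalTable, ExpressionMatrix, MatchedCohort, build_cohort
from .network import MODULE_COLORS


@dataclass
class TissueConfig:
    """Per-tissue gene layout: module sizes, factor strength, noise."""

    n_genes: int = 1000
    module_sizes: list = field(default_factory=lambda: [150, 120, 100, 80, 60, 40])
    module_corr: float = 0.6        # target mean within-module |correlation|
    neg_loading_frac: float = 0.2   # fraction of members loading negatively
    noise_sd: float = 1.0

    def __post_init__(self):
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        if not 0 < self.module_corr < 1:
            raise ValueError("module_corr must be in (0, 1)")

    @property
    def module_labels(self) -> list:
        return [MODULE_COLORS[i] for i in range(len(self.module_sizes))]


@dataclass
class Interaction:
    """A planted cross-tissue factor correlation, active in one stratum."""

    tumor_module: str
    blood_module: str
    scheme: str   # "all" for an unstratified interaction
    stratum: str
    rho: float

    def __post_init__(self):
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")


@dataclass
class AttributeSpec:
    """A clinical covariate; continuous ones may track a module factor."""

    name: str
    kind: str = "continuous"            # "continuous" | "categorical"
    levels: dict = field(default_factory=dict)  # categorical: label -> prob or count
    linked: tuple = None                # (tissue, module) or None
    coef: float = 1.0
    noise_sd: float = 1.0
    loc: float = 0.0
    scale: float = 1.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_patients: int = 120
    n_controls: int = 40
    tumor: TissueConfig = field(default_factory=TissueConfig)
    blood: TissueConfig = field(default_factory=TissueConfig)
    schemes: dict = field(default_factory=dict)   # scheme -> {label: prob or count}
    interactions: list = field(default_factory=list)
    attributes: list = field(default_factory=list)

    def validate(self) -> None:
        for t in (self.tumor, self.blood):
            t.__post_init__()
        for scheme, levels in self.schemes.items():
            vals = list(levels.values())
            if all(isinstance(v, (int, np.integer)) for v in vals):
                if sum(vals) != self.n_patients:
                    raise ValueError(f"scheme {scheme!r}: counts must sum to n_patients")
            elif not np.isclose(sum(vals), 1.0):
                raise ValueError(f"scheme {scheme!r}: probabilities must sum to 1")
        used = set()
        for it in self.interactions:
            it.__post_init__()
            if it.scheme != "all" and it.scheme not in self.schemes:
                raise ValueError(f"interaction references unknown scheme {it.scheme!r}")
            if it.scheme != "all" and it.stratum not in self.schemes[it.scheme]:
                raise ValueError(f"interaction references unknown stratum {it.stratum!r}")
            if it.tumor_module not in self.tumor.module_labels:
                raise ValueError(f"unknown tumor module {it.tumor_module!r}")
            if it.blood_module not in self.blood.module_labels:
                raise ValueError(f"unknown blood module {it.blood_module!r}")
            for key in (("tumor", it.tumor_module, it.scheme, it.stratum),
                        ("blood", it.blood_module, it.scheme, it.stratum)):
                if key in used:
                    raise ValueError(f"module {key[1]!r} used twice in stratum {key[3]!r}")
                used.add(key)
        for a in self.attributes:
            if a.kind not in ("continuous", "categorical"):
                raise ValueError(f"attribute {a.name!r}: unknown kind {a.kind!r}")
            if a.linked is not None and a.kind != "continuous":
                raise ValueError("only continuous attributes may be factor-linked")

    # -- YAML round-trip --------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["interactions"] = [asdict(i) for i in self.interactions]
        doc["attributes"] = [
            {**asdict(a), "linked": list(a.linked) if a.linked else None}
            for a in self.attributes
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["tumor"] = TissueConfig(**doc.get("tumor", {}))
        doc["blood"] = TissueConfig(**doc.get("blood", {}))
        doc["interactions"] = [Interaction(**i) for i in doc.get("interactions", [])]
        doc["attributes"] = [
            AttributeSpec(**{**a, "linked": tuple(a["linked"]) if a.get("linked") else None})
            for a in doc.get("attributes", [])
        ]
        return cls(**doc)


@dataclass
class SyntheticTruth:
    """Planted structure: memberships, factors, realized interactions."""

    membership: dict       # tissue -> pd.Series gene -> module (grey for noise)
    factors: dict          # tissue -> DataFrame module x sample
    interactions: pd.DataFrame  # planted list + realized factor correlation
    attribute_linkage: dict     # attribute -> (tissue, module, coef)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _assign_labels(rng, n: int, levels: dict) -> np.ndarray:
    names = list(levels)
    vals = [levels[k] for k in names]
    if all(isinstance(v, (int, np.integer)) for v in vals):
        arr = np.repeat(names, vals)
        rng.shuffle(arr)
        return arr
    return rng.choice(names, size=n, p=np.asarray(vals, dtype=float))


def _tissue_expression(rng, cfg: TissueConfig, factors: np.ndarray,
                       gene_order: np.ndarray, sample_ids) -> tuple:
    """Expression matrix values and gene->module membership for one tissue."""
    n_samples = factors.shape[1]
    lam = np.sqrt(cfg.module_corr / (1.0 - cfg.module_corr)) * cfg.noise_sd
    x = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    membership = np.full(cfg.n_genes, "grey", dtype=object)
    pos = 0
    for mi, size in enumerate(cfg.module_sizes):
        idx = gene_order[pos:pos + size]
        pos += size
        signs = np.where(rng.random(size) < cfg.neg_loading_frac, -1.0, 1.0)
        x[idx] += signs[:, None] * lam * factors[mi][None, :]
        membership[idx] = MODULE_COLORS[mi]
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene")
    values = pd.DataFrame(x, index=genes, columns=sample_ids)
    return values, pd.Series(membership, index=genes)


def generate(config: SyntheticConfig) -> tuple:
    """Generate a (MatchedCohort, SyntheticTruth) pair from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pat, n_ctl = config.n_patients, config.n_controls
    patients = [f"P{i:04d}" for i in range(n_pat)]
    controls = [f"C{i:04d}" for i in range(n_ctl)]

    # subtype labels and categorical attributes first: factors never see them
    scheme_cols = {s: _assign_labels(rng, n_pat, lv) for s, lv in config.schemes.items()}

    # baseline independent factors, then overwrite planted interaction pairs
    f_t = rng.standard_normal((len(config.tumor.module_sizes), n_pat))
    f_b = rng.standard_normal((len(config.blood.module_sizes), n_pat))
    realized = []
    for it in config.interactions:
        if it.scheme == "all":
            mask = np.ones(n_pat, dtype=bool)
        else:
            mask = scheme_cols[it.scheme] == it.stratum
        nm = int(mask.sum())
        i_t = config.tumor.module_labels.index(it.tumor_module)
        i_b = config.blood.module_labels.index(it.blood_module)
        z1 = rng.standard_normal(nm)
        z2 = it.rho * z1 + np.sqrt(1.0 - it.rho**2) * rng.standard_normal(nm)
        f_t[i_t, mask] = z1
        f_b[i_b, mask] = z2
        realized.append({
            "tumor_module": it.tumor_module, "blood_module": it.blood_module,
            "scheme": it.scheme, "stratum": it.stratum, "rho": it.rho,
            "n_stratum": nm,
            "realized_corr": float(np.corrcoef(z1, z2)[0, 1]) if nm >= 3 else np.nan,
        })
    # controls: baseline blood factors, stratum-independent
    f_b_ctl = rng.standard_normal((len(config.blood.module_sizes), n_ctl))

    # gene->module maps: independent random permutations of the shared namespace
    order_t = rng.permutation(config.tumor.n_genes)
    order_b = rng.permutation(config.blood.n_genes)
    vals_t, mem_t = _tissue_expression(rng, config.tumor, f_t, order_t, patients)
    f_b_all = np.concatenate([f_b, f_b_ctl], axis=1)
    vals_b, mem_b = _tissue_expression(rng, config.blood, f_b_all, order_b,
                                       patients + controls)

    # clinical table
    clin = {}
    for scheme, labels in scheme_cols.items():
        clin[scheme] = labels
    types = {s: "categorical" for s in scheme_cols}
    linkage = {}
    for a in config.attributes:
        if a.kind == "categorical":
            clin[a.name] = _assign_labels(rng, n_pat, a.levels)
            types[a.name] = "categorical"
        else:
            base = rng.normal(a.loc, a.scale, size=n_pat)
            if a.linked is not None:
                tissue, module = a.linked
                f = {"tumor": f_t, "blood": f_b}[tissue]
                mi = {"tumor": config.tumor, "blood": config.blood}[tissue].module_labels.index(module)
                base = a.loc + a.coef * f[mi] + rng.normal(0.0, a.noise_sd, size=n_pat)
                linkage[a.name] = (tissue, module, a.coef)
            clin[a.name] = base
            types[a.name] = "continuous"
    clinical = ClinicalTable(
        pd.DataFrame(clin, index=pd.Index(patients, name="patient_id")), types)

    tumor = ExpressionMatrix(vals_t, "tumor", pd.Series("patient", index=vals_t.columns))
    roles_b = pd.Series(["patient"] * n_pat + ["control"] * n_ctl, index=vals_b.columns)
    blood = ExpressionMatrix(vals_b, "blood", roles_b)
    cohort = build_cohort(tumor, blood, clinical)

    truth = SyntheticTruth(
        membership={"tumor": mem_t, "blood": mem_b},
        factors={
            "tumor": pd.DataFrame(f_t, index=config.tumor.module_labels, columns=patients),
            "blood": pd.DataFrame(f_b_all, index=config.blood.module_labels,
                                  columns=patients + controls),
        },
        interactions=pd.DataFrame(
            realized, columns=["tumor_module", "blood_module", "scheme", "stratum",
                               "rho", "n_stratum", "realized_corr"]),
        attribute_linkage=linkage,
    )
    return cohort, truth


def null_cohort(config: SyntheticConfig) -> MatchedCohort:
    """Same generator with every cross-tissue factor independent.

    Used for type-I error calibration of the interaction caller.
    """
    import copy

    cfg = copy.deepcopy(config)
    cfg.interactions = []
    cohort, _ = generate(cfg)
    return cohort


# ---------------------------------------------------------------------------
# canned configurations (study-condition scenarios)
# ---------------------------------------------------------------------------

def demo_config(seed: int = 0) -> SyntheticConfig:
    """End-to-end demo cohort: 2x1000 genes, 120 patients, 40 controls,
    6 modules per tissue, 2 subtype-specific planted interactions."""
    return SyntheticConfig(
        seed=seed, n_patients=120, n_controls=40,
        tumor=TissueConfig(), blood=TissueConfig(),
        schemes={
            "pam50": {"basal": 40, "lumA": 40, "lumB": 40},
            "clinical": {"ERpos": 0.6, "ERneg": 0.35, "rare": 0.05},
        },
        interactions=[
            Interaction("turquoise", "blue", "pam50", "basal", 0.7),
            Interaction("brown", "green", "pam50", "lumB", -0.7),
        ],
        attributes=[
            AttributeSpec("age", loc=55.0, scale=8.0),
            AttributeSpec("MKS", linked=("tumor", "turquoise"), coef=1.0, noise_sd=0.5),
            AttributeSpec("lymph", kind="categorical",
                          levels={"node_neg": 0.6, "node_pos": 0.4}),
        ],
    )


def module_recovery_config(seed: int = 0, n_modules: int = 5, module_size: int = 100,
                           corr: float = 0.6, n_patients: int = 150,
                           n_noise: int = 0) -> SyntheticConfig:
    """The standard module-recovery scenario (planted blocks, no interactions)."""
    tissue = TissueConfig(
        n_genes=n_modules * module_size + n_noise,
        module_sizes=[module_size] * n_modules,
        module_corr=corr,
    )
    import copy
    return SyntheticConfig(seed=seed, n_patients=n_patients, n_controls=0,
                           tumor=tissue, blood=copy.deepcopy(tissue))


def interaction_power_config(seed: int = 0, rho: float = 0.7) -> SyntheticConfig:
    """Planted subtype-specific interaction, stratum n=40 (power scenario)."""
    tissue = TissueConfig(n_genes=450, module_sizes=[100, 100, 100, 100],
                         module_corr=0.6)
    import copy
    return SyntheticConfig(
        seed=seed, n_patients=120, n_controls=0,
        tumor=tissue, blood=copy.deepcopy(tissue),
        schemes={"pam50": {"basal": 40, "lumA": 40, "lumB": 40}},
        interactions=[Interaction("turquoise", "blue", "pam50", "basal", rho)],
    )


def null_calibration_config(seed: int = 0, n_modules: int = 12,
                            module_size: int = 60) -> SyntheticConfig:
    """No planted interactions; two 3-level schemes for many strata."""
    tissue = TissueConfig(n_genes=n_modules * module_size,
                         module_sizes=[module_size] * n_modules,
                         module_corr=0.6)
    import copy
    return SyntheticConfig(
        seed=seed, n_patients=120, n_controls=0,
        tumor=tissue, blood=copy.deepcopy(tissue),
        schemes={
            "scheme_a": {"a1": 40, "a2": 40, "a3": 40},
            "scheme_b": {"b1": 60, "b2": 30, "b3": 30},
        },
    )
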