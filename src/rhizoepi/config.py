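"""Simulation and pipeline configuration.

All tunables of the synthetic genome generator live here as nested
dataclasses with validated defaults. The defaults define the study
conditions the analysis is exercised under: a ~2-Mb genome over four
chromosomes plus a small mitochondrial contig, ~500 TE copies drawn from
eight families in two divergence waves, ~800 genes across the core/orphan/
expanded classes with a fraction of expanded-family genes planted next to
MULE copies, bimodal CpG methylation conditioned on feature class, 24-nt
U/A-biased small RNAs from young TEs, and a 5-condition x 4-replicate
negative-binomial expression design with planted fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TEFamily:
    name: str
    superfamily: str
    consensus_length: int

    def validate(self) -> None:
        if self.consensus_length <= 0:
            raise ConfigurationError(f"{self.name}: consensus length must be positive")


@dataclass
class CopyPlan:
    """How many copies of one family to plant and at which divergences.

    Either ``k_values`` fixes the target Kimura distance of every copy, or
    copies are drawn from a two-wave mixture: ``young_fraction`` of copies
    uniform on ``k_young`` and the rest uniform on ``k_old``.
    """

    n_copies: int = 60
    k_values: list[float] | None = None
    k_young: tuple[float, float] = (0.01, 0.08)
    k_old: tuple[float, float] = (0.15, 0.35)
    young_fraction: float = 0.5
    length_fraction: tuple[float, float] = (0.08, 0.30)

    def validate(self) -> None:
        if self.n_copies < 0:
            raise ConfigurationError("n_copies must be >= 0")
        if self.k_values is not None and any(k < 0 for k in self.k_values):
            raise ConfigurationError("planted K must be >= 0")
        if not 0 <= self.young_fraction <= 1:
            raise ConfigurationError("young_fraction must lie in [0, 1]")
        lo, hi = self.length_fraction
        if not 0 < lo <= hi <= 1:
            raise ConfigurationError("length_fraction must lie in (0, 1]")


@dataclass
class GenePlan:
    """Gene counts per class and the MULE-proximity rule for expanded genes."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "A": 400,
            "B_LCN": 150,
            "B_HCN": 100,
            "C_STY_kinase": 25,
            "C_CaM_kinase": 20,
            "C_BTB_POZ": 20,
            "C_Sel1": 20,
            "C_Kelch": 15,
            "crinkler": 10,
            "transposon_related": 40,
        }
    )
    length_range: tuple[int, int] = (600, 1500)
    #: fraction of Class C genes planted within ``mule_distance`` bp of a MULE copy
    near_mule_fraction: float = 0.6
    mule_distance: int = 500
    #: gaps flanking Class A genes are shrunk by this factor (two-speed layout)
    class_a_gap_weight: float = 0.3
    p_expressed: dict[str, float] = field(
        default_factory=lambda: {
            "A": 0.9,
            "B_LCN": 0.4,
            "B_HCN": 0.4,
            "C": 0.7,
            "crinkler": 0.5,
            "transposon_related": 0.3,
        }
    )

    def validate(self) -> None:
        if any(n < 0 for n in self.class_counts.values()):
            raise ConfigurationError("gene counts must be >= 0")
        if not 0 <= self.near_mule_fraction <= 1:
            raise ConfigurationError("near_mule_fraction must lie in [0, 1]")
        if self.mule_distance <= 0:
            raise ConfigurationError("mule_distance must be positive")
        if any(not 0 <= p <= 1 for p in self.p_expressed.values()):
            raise ConfigurationError("p_expressed values must lie in [0, 1]")


@dataclass
class MethylationModel:
    """Two-component beta mixture with per-feature-class high-state weights."""

    high: tuple[float, float] = (50.0, 2.0)
    low: tuple[float, float] = (2.0, 50.0)
    p_high: dict[str, float] = field(
        default_factory=lambda: {
            "TE_expressed": 0.10,
            "TE_nonexpressed": 0.90,
            "A": 0.05,
            "B_LCN": 0.50,
            "B_HCN": 0.55,
            "C": 0.20,
            "crinkler": 0.30,
            "transposon_related": 0.80,
            "background": 0.25,
        }
    )
    coverage_mean: float = 20.0

    def validate(self) -> None:
        for a, b in (self.high, self.low):
            if a <= 0 or b <= 0:
                raise ConfigurationError("beta parameters must be positive")
        if any(not 0 <= p <= 1 for p in self.p_high.values()):
            raise ConfigurationError("mixing probabilities must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")


@dataclass
class SrnaModel:
    """Small-RNA locus and read model.

    Producing loci come preferentially from TE copies younger than
    ``young_k_cutoff`` (Kimura distance, substitutions/site), with additional
    genic, unannotated and mitochondrial loci. Read lengths peak at 24 nt and
    first nucleotides are U/A-biased. Planted-enriched loci are scaled up by
    ``enrich_factor`` in the treated (periodate-oxidized and TraPR) libraries;
    mitochondrial loci are scaled down by ``mito_depletion`` there.
    """

    young_k_cutoff: float = 0.10
    p_locus_per_young_te: float = 0.6
    locus_length: tuple[int, int] = (80, 400)
    n_genic_loci: int = 25
    n_unannotated_loci: int = 100
    #: fraction of unannotated loci planted within ``near_te_distance`` bp of
    #: a TE copy (intergenic sRNA production clusters around TEs)
    unannotated_near_te_fraction: float = 1.0
    near_te_distance: int = 60
    n_mito_loci: int = 8
    reads_per_locus_mean: float = 60.0
    reads_per_locus_sigma: float = 0.8
    mito_read_multiplier: float = 8.0
    length_probs: dict[int, float] = field(
        default_factory=lambda: {
            20: 0.03, 21: 0.05, 22: 0.08, 23: 0.15,
            24: 0.45, 25: 0.15, 26: 0.07, 27: 0.02,
        }
    )
    first_nt_probs: dict[str, float] = field(
        default_factory=lambda: {"T": 0.5, "A": 0.3, "C": 0.1, "G": 0.1}
    )
    majority_strand_fraction: float = 0.9
    enriched_fraction: float = 0.30
    depleted_fraction: float = 0.10
    enrich_factor: float = 4.0
    mito_depletion: float = 0.05
    n_replicates: int = 3

    def validate(self) -> None:
        for probs in (self.length_probs, self.first_nt_probs):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError("probabilities must be >= 0")
        if self.young_k_cutoff < 0:
            raise ConfigurationError("young_k_cutoff must be >= 0")
        if not 0 <= self.mito_depletion <= 1:
            raise ConfigurationError("mito_depletion must lie in [0, 1]")
        if self.enrich_factor <= 0:
            raise ConfigurationError("enrich_factor must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per library for enrichment tests")


CONDITIONS = ("0h", "24h_mock", "24h_exudate", "48h_mock", "48h_exudate")


@dataclass
class ExpressionDesign:
    """Five conditions x four replicates with negative-binomial counts."""

    conditions: tuple[str, ...] = CONDITIONS
    n_replicates: int = 4
    dispersion: float = 0.1
    expressed_mean: float = 150.0
    expressed_sigma: float = 0.7
    silent_gene_mean: float = 0.1
    silent_te_mean: float = 0.05
    subfamily_mean: float = 400.0
    #: planted log2 fold changes per TE subfamily, applied in every non-control condition
    planted_log2fc: dict[str, float] = field(
        default_factory=lambda: {"MULE1": 2.0, "Gypsy1": -2.0}
    )

    def validate(self) -> None:
        if len(self.conditions) * self.n_replicates != 20:
            raise ConfigurationError("design must have exactly 20 samples (5 conditions x 4 replicates)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")


DEFAULT_TE_LIBRARY: tuple[TEFamily, ...] = (
    TEFamily("MULE1", "DNA/MULE-MuDR", 3000),
    TEFamily("CMC1", "DNA/CMC-EnSpm", 2500),
    TEFamily("hAT1", "DNA/hAT", 2000),
    TEFamily("TcMar1", "DNA/TcMar", 1800),
    TEFamily("Gypsy1", "LTR/Gypsy", 5000),
    TEFamily("Copia1", "LTR/Copia", 4500),
    TEFamily("LINE1", "LINE/R1", 4000),
    TEFamily("Helitron1", "RC/Helitron", 3500),
)


def default_copy_plan() -> dict[str, CopyPlan]:
    plan = {fam.name: CopyPlan(n_copies=60) for fam in DEFAULT_TE_LIBRARY}
    plan["MULE1"] = CopyPlan(n_copies=80, young_fraction=0.6)
    return plan


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 500_000
    mito_length: int = 30_000
    gc_content: float = 0.40
    transversion_transition_ratio: float = 0.5  # Q = ratio * P
    p_expressed_young_te: float = 0.5
    p_expressed_old_te: float = 0.15
    te_library: tuple[TEFamily, ...] = DEFAULT_TE_LIBRARY
    copy_plan: dict[str, CopyPlan] = field(default_factory=default_copy_plan)
    gene_plan: GenePlan = field(default_factory=GenePlan)
    methylation_model: MethylationModel = field(default_factory=MethylationModel)
    srna_model: SrnaModel = field(default_factory=SrnaModel)
    expression_design: ExpressionDesign = field(default_factory=ExpressionDesign)

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length <= 0 or self.mito_length <= 0:
            raise ConfigurationError("all lengths must be positive")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must lie in (0, 1)")
        if self.transversion_transition_ratio < 0:
            raise ConfigurationError("transversion:transition ratio must be >= 0")
        names = [f.name for f in self.te_library]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate TE family names")
        for fam in self.te_library:
            fam.validate()
        for name in self.copy_plan:
            if name not in names:
                raise ConfigurationError(f"copy plan references unknown family {name!r}")
            self.copy_plan[name].validate()
        self.gene_plan.validate()
        self.methylation_model.validate()
        self.srna_model.validate()
        self.expression_design.validate()

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        """Build a config from a flat YAML mapping; unknown keys are rejected.

        Nested sections (gene_plan, methylation_model, srna_model,
        expression_design, copy_plan entries) accept partial mappings merged
        over the defaults; te_library entries are (name, superfamily,
        consensus_length) mappings.
        """
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config must be a mapping")
        cfg = cls()
        nested = {
            "gene_plan": GenePlan,
            "methylation_model": MethylationModel,
            "srna_model": SrnaModel,
            "expression_design": ExpressionDesign,
        }
        for key, value in data.items():
            if key in nested:
                section = getattr(cfg, key)
                for k, v in (value or {}).items():
                    if not hasattr(section, k):
                        raise ConfigurationError(f"unknown key {key}.{k}")
                    setattr(section, k, v)
            elif key == "te_library":
                cfg.te_library = tuple(TEFamily(**f) for f in value)
            elif key == "copy_plan":
                cfg.copy_plan = {name: CopyPlan(**(v or {})) for name, v in value.items()}
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return yaml.safe_dump(plain(asdict(self)), sort_keys=False)
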