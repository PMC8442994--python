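"""Synthetic RT-qPCR datasets for a MADS-box inflorescence time course.

The generator emulates the structure of a barley MIKCc MADS-box profiling
experiment: ~30 genes measured by quantification cycle (Cq) over eleven
Waddington stages and five floral organs, with three technical replicates,
a four-candidate reference panel containing one destabilized candidate,
three tightly co-expressed temporal blocks, a loosely correlated early
"pseudoset" block, independent ungrouped genes, and one antisense-overlap
assay pair (a target whose measured signal is contaminated by a neighbouring
transcript on the opposite strand, plus a background-only assay).

The forward model is ``Cq = base_cq - log2(expression) + noise``; an
expression value below a small fraction of the gene's maximum is emitted as
a missing Cq (no amplification). Ground truth (group labels, ABCDE class
labels and noise-free profiles) is returned alongside, so that downstream
normalization, co-expression grouping and conformance reporting can be
tested for exact recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .stages import DEFAULT_GRID, ORGANS, StageGrid

GROUPS = ("set1", "set2", "set3", "pseudoset", "ungrouped", "reference")

#: organ sets used to build noise-free organ profiles, per ABCDE class
CLASS_ORGANS = {
    "A": ("lemma", "palea", "lodicule"),
    "B": ("lodicule", "stamen"),
    "C": ("stamen", "carpel"),
    "D": ("carpel",),
    "E-LOFSEP": ("lemma", "palea"),
    "E-SEP3": ("lodicule", "stamen", "carpel"),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic time-course experiment.

    Noise quantities in cycles refer to the Cq scale; dimensionless ones are
    multiplicative (log-normal) perturbations of expression.
    """

    n_genes_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "set1": 3, "set2": 8, "set3": 7, "pseudoset": 6, "ungrouped": 3,
        }
    )
    grid: StageGrid = DEFAULT_GRID
    #: candidate reference genes and their per-condition Cq instability (cycles)
    reference_panel: dict[str, float] = field(
        default_factory=lambda: {
            "GAPDH": 0.8, "CYCLO": 0.05, "TUBULIN": 0.06, "HSP70": 0.07,
        }
    )
    replicate_sd: float = 0.1          # technical-replicate Cq noise, cycles
    biological_jitter_sd: float = 0.06  # per-gene, per-stage template jitter
    gene_scale_sigma: float = 0.8      # log-normal spread of per-gene abundance
    organ_noise_sd: float = 0.2        # multiplicative noise on organ weights
    base_cq: float = 22.0              # Cq anchoring expression 1.0
    n_replicates: int = 3
    overlap_pair: tuple[str, str] = ("PI2", "PKIN")
    overlap_background_amplitude: float = 0.5
    resurgence_enabled: bool = False
    missing_floor_frac: float = 2.0 ** -15
    #: (gene, organ, weight) overrides injected into the organ truth;
    #: the default plants C-class transcript in the lodicules.
    organ_deviations: tuple[tuple[str, str, float], ...] = (
        ("AGC1", "lodicule", 1.0),
    )

    def __post_init__(self) -> None:
        for g in self.n_genes_per_group:
            if g not in GROUPS or g == "reference":
                raise ConfigError(f"unknown gene group {g!r}")
        for name, val in [
            ("replicate_sd", self.replicate_sd),
            ("biological_jitter_sd", self.biological_jitter_sd),
            ("gene_scale_sigma", self.gene_scale_sigma),
            ("organ_noise_sd", self.organ_noise_sd),
        ]:
            if val < 0:
                raise ConfigError(f"{name} must be >= 0, got {val}")
        for ref, sd in self.reference_panel.items():
            if sd < 0:
                raise ConfigError(f"reference {ref!r} noise sd must be >= 0")
        if len(self.reference_panel) != 4:
            raise ConfigError("reference panel must contain exactly 4 candidates")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid"] = {"labels": list(self.grid.labels),
                     "values": list(self.grid.values)}
        d["n_genes_per_group"] = dict(self.n_genes_per_group)
        d["organ_deviations"] = [list(t) for t in self.organ_deviations]
        d["overlap_pair"] = list(self.overlap_pair)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "grid" in d:
            g = d["grid"]
            d["grid"] = StageGrid(tuple(g["labels"]), tuple(g["values"]))
        if "organ_deviations" in d:
            d["organ_deviations"] = tuple(tuple(t) for t in d["organ_deviations"])
        if "overlap_pair" in d:
            d["overlap_pair"] = tuple(d["overlap_pair"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Noise-free profiles and labels emitted alongside a synthetic dataset."""

    group_of: dict[str, str]
    class_of: dict[str, str]
    true_profile: pd.DataFrame    # genes x stage labels
    true_organ: pd.DataFrame      # genes x organs
    background_name: str
    background_profile: pd.Series
    background_organ: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.true_profile.index)


# ---------------------------------------------------------------------------
# stage templates

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((s - center) ** 2) / (2.0 * width * width))


def set1_template(s: np.ndarray) -> np.ndarray:
    """Exponential decline from the floral transition, half-life 0.5 stages."""
    return np.exp(-(s - s[0]) * np.log(2.0) / 0.5)


def set2_template(s: np.ndarray) -> np.ndarray:
    """Rise from floral-organ initiation, peak before anthesis, sharp
    post-pollination drop."""
    return _logistic((s - 4.0) / 1.2) * _logistic(-(s - 10.2) / 0.12)


def set3_template(s: np.ndarray) -> np.ndarray:
    """Late rise, still increasing after pollination."""
    return _logistic((s - 8.5) / 0.8)


# Pseudoset genes share a broad early bump (spikelet/floret-meristem window)
# plus a per-gene spike at a distinct early stage. Spike heights are chosen
# so that noise-free pairwise correlations sit near 0.83 - above the
# pseudoset threshold but below the strict set threshold.
_PSEUDO_SPIKE_HEIGHTS = (0.6043, 0.6758, 0.7254, 0.6043, 0.5681, 0.5651)


def pseudoset_template(s: np.ndarray, k: int) -> np.ndarray:
    base = _bump(s, 2.5, 1.2)
    idx = 1 + (k % 6)              # W1.5 .. W4.5 on the default grid
    idx = min(idx, len(s) - 1)
    out = base.copy()
    out[idx] += _PSEUDO_SPIKE_HEIGHTS[k % 6]
    return out


# Erratic multi-phasic profiles for genes that join no set: each carries a
# weak early-development signal plus idiosyncratic mid/late excursions, so
# that correlations with every set, with the pseudoset and with each other
# stay clear of both assignment thresholds. Tabulated on the default
# Waddington grid; other grids are served by stage-value interpolation.
_UNGROUPED_STAGE_VALUES = (1, 1.5, 2, 2.5, 3.5, 4, 4.5, 6.5, 8.5, 9.5, 10.5)
_UNGROUPED_PROFILES = (
    (0.373, 0.882, 0.775, 1.0, 0.644, 0.78, 0.478, 0.827, 0.202, 0.048, 0.741),
    (0.235, 0.576, 0.945, 1.0, 0.844, 0.61, 0.189, 0.018, 0.045, 0.55, 0.929),
    (0.168, 0.863, 0.967, 1.0, 0.866, 0.47, 0.429, 0.286, 0.928, 0.081, 0.587),
)


def ungrouped_template(s: np.ndarray, k: int) -> np.ndarray:
    """Erratic shapes that fail both the strict and the pseudoset rule."""
    prof = _UNGROUPED_PROFILES[k % 3]
    return np.interp(s, _UNGROUPED_STAGE_VALUES, prof)


def _background_template(s: np.ndarray) -> np.ndarray:
    return _bump(s, 5.0, 0.9)


# Default gene roster: (name, ABCDE class or "other", organ template).
# Organ templates for ABCDE classes come from CLASS_ORGANS; "other" genes
# carry their own plausible organ sets.
_ROSTER = {
    "set1": [("SVL1", "other", ("stamen",)),
             ("SVL2", "other", ("lemma", "palea")),
             ("SVL3", "other", ("lemma", "palea"))],
    "set2": [("AP1a", "A", None), ("AP1b", "A", None), ("AP1c", "A", None),
             ("PI1", "B", None), ("PI2", "B", None), ("AP3", "B", None),
             ("AGC1", "C", None), ("SEPL1", "E-LOFSEP", None)],
    "set3": [("AGC2", "C", None), ("AGD1", "D", None), ("AGD2", "D", None),
             ("SEP3a", "E-SEP3", None), ("SEP3b", "E-SEP3", None),
             ("BS1", "other", ("carpel",)), ("BS2", "other", ("carpel",))],
    "pseudoset": [("SEPL2", "E-LOFSEP", None), ("SEPL3", "E-LOFSEP", None),
                  ("SOC1a", "other", ("lemma", "palea")),
                  ("SOC1b", "other", ("lemma", "palea")),
                  ("MBX1", "other", ("lemma", "palea", "lodicule")),
                  ("MBX2", "other", ("lemma", "palea", "lodicule"))],
    "ungrouped": [("AGL17a", "other", ()), ("AGL17b", "other", ()),
                  ("AGL17c", "other", ())],
}


def _roster(group: str, n: int) -> list[tuple[str, str, tuple | None]]:
    base = _ROSTER[group]
    out = list(base[:n])
    for i in range(len(base), n):
        out.append((f"{group}_g{i + 1}", "other", ()))
    return out


_TEMPLATES = {
    "set1": lambda s, k: set1_template(s),
    "set2": lambda s, k: set2_template(s),
    "set3": lambda s, k: set3_template(s),
    "pseudoset": pseudoset_template,
    "ungrouped": ungrouped_template,
}

# pseudoset looseness: larger per-stage jitter than the strict sets
_PSEUDO_JITTER_FACTOR = 1.15
_UNGROUPED_JITTER_SD = 0.08


def generate_truth(config: SimConfig, seed: int) -> GroundTruth:
    """Draw noise-free per-gene stage and organ profiles plus labels.

    Genes within each strict set share a temporal template up to a per-gene
    positive scale and multiplicative jitter bounded by
    ``biological_jitter_sd``; pseudoset genes share a broad early bump with
    larger jitter; ungrouped genes are mutually independent erratic shapes.
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(config.grid.values, dtype=float)

    group_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    rows: dict[str, np.ndarray] = {}
    organ_rows: dict[str, np.ndarray] = {}

    for group in ("set1", "set2", "set3", "pseudoset", "ungrouped"):
        n = config.n_genes_per_group.get(group, 0)
        for k, (name, klass, organ_set) in enumerate(_roster(group, n)):
            template = _TEMPLATES[group](s, k)
            if group == "set1" and k == 0 and config.resurgence_enabled:
                # optional late second peak on one early gene (stressor)
                template = template + 1.2 * _bump(s, 9.5, 0.5)
            jitter_sd = config.biological_jitter_sd
            if group == "pseudoset":
                jitter_sd *= _PSEUDO_JITTER_FACTOR
            elif group == "ungrouped":
                jitter_sd = max(jitter_sd, _UNGROUPED_JITTER_SD)
            scale = float(np.exp(rng.normal(0.0, config.gene_scale_sigma)))
            jitter = np.exp(rng.normal(0.0, jitter_sd, size=len(s)))
            profile = scale * template * jitter
            if np.any(profile < 0):  # pragma: no cover - templates are >= 0
                raise RuntimeError(f"negative true expression for {name}")
            group_of[name] = group
            class_of[name] = klass
            rows[name] = profile
            organ_rows[name] = _organ_profile(
                name, klass, organ_set, scale, config, rng
            )

    for ref in config.reference_panel:
        group_of[ref] = "reference"
        class_of[ref] = "other"

    true_profile = pd.DataFrame(rows, index=list(config.grid.labels)).T
    true_organ = pd.DataFrame(organ_rows, index=list(ORGANS)).T

    bg_name = config.overlap_pair[1]
    target = config.overlap_pair[0]
    if target not in true_profile.index:
        raise ConfigError(f"overlap target {target!r} not among generated genes")
    amp = config.overlap_background_amplitude * float(
        true_profile.loc[target].max()
    )
    bg_profile = pd.Series(
        amp * _background_template(s), index=list(config.grid.labels)
    )
    bg_organ = pd.Series(
        amp * np.array([0.1, 0.1, 0.2, 1.0, 0.3]), index=list(ORGANS)
    )
    return GroundTruth(
        group_of=group_of,
        class_of=class_of,
        true_profile=true_profile,
        true_organ=true_organ,
        background_name=bg_name,
        background_profile=bg_profile,
        background_organ=bg_organ,
    )


def _organ_profile(name, klass, organ_set, scale, config, rng) -> np.ndarray:
    expected = CLASS_ORGANS.get(klass, organ_set or ())
    weights = np.array(
        [1.0 if o in expected else 0.01 for o in ORGANS], dtype=float
    )
    for gene, organ, w in config.organ_deviations:
        if gene == name:
            if organ not in ORGANS:
                raise ConfigError(f"unknown organ {organ!r} in organ_deviations")
            weights[ORGANS.index(organ)] = w
    noise = np.exp(rng.normal(0.0, config.organ_noise_sd, size=len(ORGANS)))
    return scale * weights * noise


# ---------------------------------------------------------------------------
# forward model: expression -> Cq


def truth_to_cq(truth: GroundTruth, config: SimConfig, seed: int) -> pd.DataFrame:
    """Emit a long-format Cq table from ground-truth expression.

    ``Cq = base_cq - log2(expression) + N(0, replicate_sd)`` per technical
    replicate. Reference candidates are flat at ``base_cq`` plus a
    per-condition draw of their candidate-specific noise. The overlap pair
    emits an observed assay equal to target-plus-background and an
    independent background-only assay. Expression below
    ``missing_floor_frac`` of the gene's maximum is emitted as a missing Cq.
    """
    rng = np.random.default_rng(seed)
    target, bg_name = config.overlap_pair
    records: list[tuple] = []

    def emit(gene: str, ctype: str, condition: str, expr: float, floor: float):
        for rep in range(1, config.n_replicates + 1):
            if expr < 0:
                raise RuntimeError(
                    f"negative expression for {gene} at {condition}"
                )
            if expr <= floor or expr == 0.0:
                records.append((gene, ctype, condition, rep, np.nan))
            else:
                noise = rng.normal(0.0, config.replicate_sd) \
                    if config.replicate_sd > 0 else 0.0
                cq = config.base_cq - np.log2(expr) + noise
                records.append((gene, ctype, condition, rep, cq))

    batches = [
        ("stage", list(config.grid.labels), truth.true_profile,
         truth.background_profile),
        ("organ", list(ORGANS), truth.true_organ, truth.background_organ),
    ]
    for ctype, conditions, table, bg in batches:
        for gene in table.index:
            expr_row = table.loc[gene].to_numpy(dtype=float)
            if gene == target:
                expr_row = expr_row + bg.to_numpy(dtype=float)
            floor = config.missing_floor_frac * float(np.max(expr_row))
            for cond, expr in zip(conditions, expr_row):
                emit(gene, ctype, cond, float(expr), floor)
        # background-only assay
        bg_vals = bg.to_numpy(dtype=float)
        floor = config.missing_floor_frac * float(np.max(bg_vals))
        for cond, expr in zip(conditions, bg_vals):
            emit(bg_name, ctype, cond, float(expr), floor)
        # reference candidates: flat, with per-condition instability
        for ref, cond_sd in config.reference_panel.items():
            for cond in conditions:
                shift = rng.normal(0.0, cond_sd) if cond_sd > 0 else 0.0
                for rep in range(1, config.n_replicates + 1):
                    noise = rng.normal(0.0, config.replicate_sd) \
                        if config.replicate_sd > 0 else 0.0
                    records.append(
                        (ref, ctype, cond, rep, config.base_cq + shift + noise)
                    )

    return pd.DataFrame.from_records(
        records, columns=["gene", "condition_type", "condition", "replicate", "cq"]
    )


def simulate_dataset(config: SimConfig, seed: int) -> tuple[GroundTruth, pd.DataFrame]:
    """Generate ground truth and the matching Cq table with one seed.

    Two child seeds (truth, measurement noise) are spawned deterministically
    from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    truth_seed, cq_seed = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]
    truth = generate_truth(config, truth_seed)
    cq = truth_to_cq(truth, config, cq_seed)
    return truth, cq


# ---------------------------------------------------------------------------
# text IO


def write_cq_tsv(cq: pd.DataFrame, path) -> None:
    """Write a Cq table; a missing Cq becomes an empty field."""
    cq.to_csv(path, sep="\t", index=False, na_rep="")


def read_cq_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str})
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    return df


def write_truth_tsv(truth: GroundTruth, path) -> None:
    rows = []
    for gene in truth.genes:
        for cond, val in truth.true_profile.loc[gene].items():
            rows.append((gene, truth.group_of[gene], truth.class_of[gene],
                         "stage", cond, val))
        for cond, val in truth.true_organ.loc[gene].items():
            rows.append((gene, truth.group_of[gene], truth.class_of[gene],
                         "organ", cond, val))
    pd.DataFrame(
        rows, columns=["gene", "group", "class", "condition_type", "condition",
                       "value"]
    ).to_csv(path, sep="\t", index=False)
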