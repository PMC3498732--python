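"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate a combined chemostat + retentostat transcriptome
study design: 22 arrays spanning chemostats at mu = 0.2, 0.1, 0.05,
0.03 and 0.025 h-1 (3/3/2/3/3 replicates) and duplicate retentostat
samples at days 2, 9, 16 and 22, corresponding to mu of about 0.0084,
0.0024, 0.0011 and 0.00063 h-1 — nine conditions in total.

Responder genes follow one of seven archetype profile shapes (smooth
logistic transitions in log10 mu: rising/falling with growth rate with
low-mu plateaus, glucose-derepression shapes, shifts specific to the
near-zero retentostat regime, and a near-zero-only dip).  Replicate
scatter is multiplicative lognormal at a configurable CV (default 14%,
the typical reproducibility of replicate steady-state arrays);
housekeeping genes are constant-mean at lower noise, null genes
constant-mean at full noise.  Every generator is bit-reproducible at a
fixed seed and returns a truth table sufficient to score sensitivity and
FDR of each downstream stage.

Also generated: model-consistent retentostat biomass/viability curves,
annotation collections with planted enrichments, and promoter sequences
with a planted IUPAC motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, Motif
from .kinetics import BiomassTimeSeries, RetentostatParams, predict_biomass

__all__ = [
    "DesignSpec",
    "ArchetypeSpec",
    "DEFAULT_ARCHETYPES",
    "NoiseSpec",
    "generate_expression",
    "generate_retentostat_series",
    "generate_gene_sets",
    "generate_promoters",
]


@dataclass(frozen=True)
class DesignSpec:
    """The 22-array combined chemostat + retentostat design."""

    chemostat_rates: tuple = (0.2, 0.1, 0.05, 0.03, 0.025)
    chemostat_replicates: tuple = (3, 3, 2, 3, 3)
    retentostat_days: tuple = (2, 9, 16, 22)
    retentostat_rates: tuple = (0.0084, 0.0024, 0.0011, 0.00063)
    retentostat_replicates: int = 2

    def __post_init__(self) -> None:
        if len(self.chemostat_rates) != len(self.chemostat_replicates):
            raise ValueError("chemostat rates and replicate counts differ in length")
        if len(self.retentostat_days) != len(self.retentostat_rates):
            raise ValueError("retentostat days and rates differ in length")
        if np.any(np.diff(self.retentostat_rates) >= 0):
            raise ValueError("retentostat rates must be strictly decreasing over days")

    @property
    def n_samples(self) -> int:
        return int(sum(self.chemostat_replicates)) + self.retentostat_replicates * len(
            self.retentostat_days
        )

    @property
    def condition_rates(self) -> np.ndarray:
        """Growth rate of each condition, chemostats then retentostat days."""
        return np.array(list(self.chemostat_rates) + list(self.retentostat_rates))

    def metadata(self) -> pd.DataFrame:
        rows = []
        for rate, reps in zip(self.chemostat_rates, self.chemostat_replicates):
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"chem_mu{rate:g}_r{r}",
                        "growth_rate": rate,
                        "mode": "chemostat",
                        "replicate": r,
                        "time_d": np.nan,
                    }
                )
        for day, rate in zip(self.retentostat_days, self.retentostat_rates):
            for r in range(1, self.retentostat_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"ret_d{day:02d}_r{r}",
                        "growth_rate": rate,
                        "mode": "retentostat",
                        "replicate": r,
                        "time_d": float(day),
                    }
                )
        return pd.DataFrame(rows)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class ArchetypeSpec:
    """One of the seven cluster profile shapes.

    Shapes are smooth logistic (or Gaussian, for the dip) transitions in
    x = log10(mu) with midpoint ``mu_star`` and ``steepness`` in log10
    units; ``sign`` +1 means expression increases with growth rate across
    the transition, -1 the opposite.
    """

    archetype_id: int
    shape: str
    mu_star: float
    steepness: float
    amplitude: float = 240.0
    baseline: float = 60.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.baseline <= 0:
            raise ValueError("amplitude and baseline must be > 0")

    def profile(self, rates: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(rates, dtype=float))
        z = (x - np.log10(self.mu_star)) / self.steepness
        if self.shape == "dip":
            core = 1.0 - 0.8 * np.exp(-(z**2))
        else:
            core = _logistic(z) if self.sign > 0 else 1.0 - _logistic(z)
        return self.baseline + self.amplitude * core


#: The seven default archetypes: (1) rising with mu, plateau at low mu;
#: (2) falling with mu, plateau at low mu; (3) derepressed at low glucose
#: then constant; (4) retentostat-specific up-shift; (5) broad monotone
#: stress shape, down with mu; (6) retentostat-specific down-shift;
#: (7) near-zero-only dip.
DEFAULT_ARCHETYPES: tuple = (
    ArchetypeSpec(1, "rising_plateau", mu_star=0.01, steepness=0.35, sign=+1),
    ArchetypeSpec(2, "falling_plateau", mu_star=0.005, steepness=0.30, sign=-1),
    ArchetypeSpec(3, "derepressed_low_glucose", mu_star=0.05, steepness=0.25, sign=-1),
    ArchetypeSpec(4, "retentostat_up", mu_star=0.004, steepness=0.15, sign=-1),
    ArchetypeSpec(5, "stress_monotone_down", mu_star=0.02, steepness=0.80, sign=-1),
    ArchetypeSpec(6, "retentostat_down", mu_star=0.004, steepness=0.15, sign=+1),
    ArchetypeSpec(7, "dip", mu_star=0.002, steepness=0.25),
)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model: multiplicative lognormal, CV-specified."""

    replicate_cv: float = 0.14
    housekeeping_cv: float = 0.10
    housekeeping_cv_max: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.replicate_cv < 1:
            raise ValueError("replicate_cv must lie in [0, 1)")


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def generate_expression(
    design: DesignSpec | None = None,
    archetypes: Sequence[ArchetypeSpec] = DEFAULT_ARCHETYPES,
    n_genes_per_archetype: int = 100,
    n_housekeeping: int = 6,
    n_null: int = 300,
    noise: NoiseSpec | None = None,
    n_decoy_features: int = 0,
    target_mean: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the genes x samples intensity matrix plus truth table.

    Responder genes follow their archetype profile evaluated at the
    design's growth rates, scaled by a gene-specific lognormal factor;
    housekeeping and null genes are constant-mean.  ``n_decoy_features``
    adds non-ORF control features (for the ORF-selection step).  Array
    mean intensity is scaled to ``target_mean`` pre-noise.

    Returns ``(matrix, metadata, truth)``; truth records per gene the
    archetype, responder / housekeeping / ORF status.
    """
    design = design or DesignSpec()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    meta = design.metadata()
    rates = meta["growth_rate"].to_numpy(dtype=float)

    gene_ids: list = []
    means: list = []
    truth_rows: list = []

    for arch in archetypes:
        base_profile = arch.profile(design.condition_rates)
        # evaluate at per-sample rates (replicates share the condition mean)
        sample_profile = arch.profile(rates)
        scales = rng.lognormal(mean=0.0, sigma=0.3, size=n_genes_per_archetype)
        for i, s in enumerate(scales):
            gid = f"ARCH{arch.archetype_id}_{i:04d}"
            gene_ids.append(gid)
            means.append(s * sample_profile)
            truth_rows.append(
                {"gene_id": gid, "archetype": arch.archetype_id,
                 "is_responder": True, "is_housekeeping": False, "is_orf": True}
            )
        del base_profile
    hk_levels = rng.uniform(np.log(100), np.log(400), size=n_housekeeping)
    for i, lv in enumerate(np.exp(hk_levels)):
        gid = f"HK_{i:03d}"
        gene_ids.append(gid)
        means.append(np.full(len(rates), lv))
        truth_rows.append(
            {"gene_id": gid, "archetype": 0,
             "is_responder": False, "is_housekeeping": True, "is_orf": True}
        )
    null_levels = np.exp(rng.uniform(np.log(30), np.log(600), size=n_null))
    for i, lv in enumerate(null_levels):
        gid = f"NULL_{i:04d}"
        gene_ids.append(gid)
        means.append(np.full(len(rates), lv))
        truth_rows.append(
            {"gene_id": gid, "archetype": 0,
             "is_responder": False, "is_housekeeping": False, "is_orf": True}
        )
    decoy_levels = np.exp(rng.uniform(np.log(30), np.log(600), size=n_decoy_features))
    for i, lv in enumerate(decoy_levels):
        gid = f"AFFX_{i:04d}"
        gene_ids.append(gid)
        means.append(np.full(len(rates), lv))
        truth_rows.append(
            {"gene_id": gid, "archetype": 0,
             "is_responder": False, "is_housekeeping": False, "is_orf": False}
        )
    if not gene_ids:
        raise ValueError("zero genes requested")

    M = np.vstack(means)
    M *= target_mean / M.mean()

    truth = pd.DataFrame(truth_rows)
    hk_mask = truth["is_housekeeping"].to_numpy()
    factors = _lognormal_factors(rng, noise.replicate_cv, M.shape)
    factors_hk = _lognormal_factors(rng, noise.housekeeping_cv, M.shape)
    factors[hk_mask] = factors_hk[hk_mask]
    values = M * factors

    matrix = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"), columns=meta["sample_id"]
    )
    return matrix, meta, truth


def generate_retentostat_series(
    params: RetentostatParams | None = None,
    duration_d: float = 22.0,
    sampling_times_h: np.ndarray | None = None,
    noise_cv: float = 0.0,
    v_inf: float = 0.8,
    decay_rate: float = 0.005,
    seed: int = 0,
) -> tuple[BiomassTimeSeries, pd.DataFrame]:
    """Simulate a retentostat biomass/viability trajectory.

    The total biomass follows the closed-form maintenance-limited
    trajectory exactly (so the exponential-shape fit is well specified),
    the viable fraction decays as ``v(t) = v_inf + (1-v_inf)*exp(-decay_rate*t)``
    and multiplicative lognormal measurement noise at ``noise_cv``
    perturbs the total-biomass readings.  The truth table records the
    noiseless trajectory and the true specific growth rate
    ``mu = (dCx_total/dt)/(v*Cx_total)`` for recovery tests.
    """
    params = params or RetentostatParams(D=0.025, Cs_in=50.0)
    if not 0 < v_inf <= 1:
        raise ValueError("v_inf must lie in (0, 1]")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    if sampling_times_h is None:
        sampling_times_h = np.linspace(0.0, duration_d * 24.0, 23)
    t = np.asarray(sampling_times_h, dtype=float)

    cx_total = predict_biomass(params, t)
    v = v_inf + (1.0 - v_inf) * np.exp(-decay_rate * t)
    k = params.ms_g * params.Ysx_max
    dcx = k * (params.cx_inf - cx_total)
    mu_true = dcx / (v * cx_total)

    rng = np.random.default_rng(seed)
    observed = cx_total * _lognormal_factors(rng, noise_cv, t.shape)
    series = BiomassTimeSeries(t=t, Cx_total=observed, viability=v)
    truth = pd.DataFrame(
        {
            "time_h": t,
            "cx_total_true": cx_total,
            "viability": v,
            "cx_viable_true": v * cx_total,
            "mu_true": mu_true,
        }
    )
    return series, truth


def generate_gene_sets(
    truth: pd.DataFrame,
    n_decoy_sets: int = 10,
    set_size: int = 60,
    planted: Sequence[tuple] = (("planted_arch2", 2, 8.0),),
    seed: int = 0,
) -> tuple[GeneSetCollection, dict]:
    """Annotation sets with planted enrichment into archetype groups.

    ``planted`` lists (set_name, target archetype id, odds): members are
    sampled without replacement with weight ``odds`` for genes of the
    target archetype and 1 otherwise.  Decoy sets sample uniformly.  The
    universe is every ORF in the truth table.  Returns the collection and
    a dict set_name -> target archetype for the planted sets.
    """
    orf_truth = truth[truth["is_orf"]]
    universe = orf_truth["gene_id"].to_numpy()
    if set_size > len(universe):
        raise ValueError("requested set size exceeds the universe")
    rng = np.random.default_rng(seed)
    sets: dict = {}
    planted_map: dict = {}
    for name, arch, odds in planted:
        if set_size == 0:
            warnings.warn(f"planted set {name!r} has size 0; dropped", stacklevel=2)
            continue
        if not (orf_truth["archetype"] == arch).any():
            raise ValueError(f"archetype {arch} absent from the truth table")
        w = np.where(orf_truth["archetype"].to_numpy() == arch, float(odds), 1.0)
        members = rng.choice(universe, size=set_size, replace=False, p=w / w.sum())
        sets[name] = frozenset(members)
        planted_map[name] = arch
    for i in range(n_decoy_sets):
        members = rng.choice(universe, size=set_size, replace=False)
        sets[f"decoy_{i:03d}"] = frozenset(members)
    return GeneSetCollection(sets=sets, universe=frozenset(universe)), planted_map


def generate_promoters(
    gene_ids: Iterable,
    length: int = 800,
    gc: float = 0.38,
    motif: Motif | None = None,
    p_background: float = 0.10,
    p_planted: float = 0.40,
    planted_genes: Iterable = (),
    seed: int = 0,
    exact: bool = False,
) -> dict:
    """Random promoter sequences with a motif stamped into a subset.

    Bases are i.i.d. at the given GC content (yeast-like 0.38 default).
    Each gene receives one motif instance (random degenerate expansion,
    random strand, random offset) with probability ``p_planted`` if it is
    in ``planted_genes`` and ``p_background`` otherwise; spontaneous
    matches in the random background remain possible on top.

    With ``exact=True`` the hit *rates* are planted exactly instead:
    round(p * group size) genes per group are stamped and every other
    promoter is resampled until it is motif-free, so the scanned hit
    fractions equal the requested probabilities up to rounding.  Use this
    to construct a study condition with known hit rates.
    """
    motif = motif or Motif("TCGTTYAG")
    if not 0 <= p_background <= p_planted <= 1:
        raise ValueError("need 0 <= p_background <= p_planted <= 1")
    if len(motif.pattern) > length:
        raise ValueError("motif is longer than the promoter")
    from Bio.Seq import Seq

    from .enrichment import scan_motif

    gene_ids = list(gene_ids)
    planted = frozenset(planted_genes)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    expansions = motif.expansions()

    if exact:
        grp_planted = [g for g in gene_ids if g in planted]
        grp_bg = [g for g in gene_ids if g not in planted]
        stamped: set = set()
        for group, p in ((grp_planted, p_planted), (grp_bg, p_background)):
            n_stamp = int(round(p * len(group)))
            if n_stamp:
                stamped.update(rng.choice(group, size=n_stamp, replace=False))
        def want_stamp(gid) -> bool:
            return gid in stamped
    else:
        def want_stamp(gid) -> bool:
            p_stamp = p_planted if gid in planted else p_background
            return rng.random() < p_stamp

    out: dict = {}
    for gid in gene_ids:
        seq = rng.choice(bases, size=length, p=probs)
        if want_stamp(gid):
            inst = expansions[rng.integers(len(expansions))]
            if motif.scan_both_strands and rng.random() < 0.5:
                inst = str(Seq(inst).reverse_complement())
            off = int(rng.integers(0, length - len(inst) + 1))
            seq[off : off + len(inst)] = list(inst)
            out[gid] = "".join(seq)
        elif exact:
            s = "".join(seq)
            while scan_motif({gid: s}, motif)["hit"].iloc[0]:  # resample to motif-free
                s = "".join(rng.choice(bases, size=length, p=probs))
            out[gid] = s
        else:
            out[gid] = "".join(seq)
    return out
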