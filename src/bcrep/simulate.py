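"""Synthetic repertoire and phenotype generator with a ground-truth ledger.

Emulates the study design the analysis assumes: three adult donors, five
sorted B-cell subsets (naive, IgM_lo, IgM_hi, IgM_only, switched), heavy-chain
rearrangement tables with subset-specific V/J usage, subset-specific somatic
hypermutation (per-base rate drawn from a Beta distribution over a fixed-
length V region), heavy-tailed lineage read counts (shifted negative
binomial), a junction model with N/P segment-length bookkeeping, and planted
cross-subset clonotype sharing within donors.

Default parameterization echoes the qualitative biology — naive SHM near
zero, SHM ordering IgM_lo < IgM_hi < IgM_only < switched, IGHJ6 enriched in
naive and IgM_lo cells — but all values are synthetic defaults, not estimates
from any dataset.  Germline gene names are a small bundled toy set following
IMGT nomenclature; names only are needed since no alignment is performed.

Every emitted row is covered by the :class:`GroundTruth` ledger (true gene
calls, mutation rate and count, read count, planted-sharing pattern), which
downstream recovery tests compare against pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import SUBSETS, records_from_iterable, v_family_of
from .lineage import SharingMatrix
from .stats import mutation_percent

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_repertoire",
    "PhenotypeConfig",
    "simulate_phenotype",
    "recovery_report",
    "IGHV_GENES",
    "IGHJ_GENES",
]

#: Bundled toy heavy-chain germline gene names (IMGT nomenclature).
IGHV_GENES: tuple[str, ...] = (
    "IGHV1-2", "IGHV1-18", "IGHV1-46", "IGHV1-69",
    "IGHV2-5", "IGHV2-70",
    "IGHV3-7", "IGHV3-9", "IGHV3-15", "IGHV3-21", "IGHV3-23",
    "IGHV3-30", "IGHV3-48", "IGHV3-74",
    "IGHV4-34", "IGHV4-39", "IGHV4-59",
    "IGHV5-51", "IGHV6-1", "IGHV7-4-1",
)
IGHD_GENES: tuple[str, ...] = ("IGHD2-2", "IGHD3-10", "IGHD3-22", "IGHD6-19")
IGHJ_GENES: tuple[str, ...] = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")

# non-stop codons of the standard genetic code
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_CODON_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _default_v_usage() -> dict[str, np.ndarray]:
    base = np.array(
        [6, 4, 4, 7, 2, 2, 8, 4, 3, 5, 10, 8, 4, 4, 6, 4, 6, 4, 3, 2], dtype=float
    )
    usage: dict[str, np.ndarray] = {}
    for subset in SUBSETS:
        w = base.copy()
        if subset == "naive":
            w[IGHV_GENES.index("IGHV1-69")] *= 2.0       # naive-enriched
        if subset == "IgM_hi":
            w[IGHV_GENES.index("IGHV3-7")] *= 1.8
            w[IGHV_GENES.index("IGHV3-74")] *= 1.6
            w[IGHV_GENES.index("IGHV6-1")] *= 1.8
        if subset == "switched":
            w[IGHV_GENES.index("IGHV1-2")] *= 1.5
        usage[subset] = w / w.sum()
    return usage


def _default_j_usage() -> dict[str, np.ndarray]:
    base = np.array([4, 6, 9, 38, 17, 26], dtype=float)  # J1..J6
    usage: dict[str, np.ndarray] = {}
    for subset in SUBSETS:
        w = base.copy()
        if subset in ("naive", "IgM_lo"):
            w[5] *= 1.5                                   # IGHJ6 enrichment
        if subset == "IgM_hi":
            w[5] *= 0.6
            w[3] *= 1.2                                   # IGHJ4
        usage[subset] = w / w.sum()
    return usage


#: Per-subset Beta(alpha, beta) parameters of the per-base SHM rate; means
#: 0.2 / 2 / 4 / 5 / 6 percent reflecting the naive < IgM_lo < IgM_hi <
#: IgM_only < switched ordering.
DEFAULT_SHM: dict[str, tuple[float, float]] = {
    "naive": (1.0, 499.0),
    "IgM_lo": (2.0, 98.0),
    "IgM_hi": (4.0, 96.0),
    "IgM_only": (5.0, 95.0),
    "switched": (6.0, 94.0),
}

#: Default planted within-donor sharing: exact clonotype counts per pattern,
#: per donor.
DEFAULT_SHARING: dict[frozenset, int] = {
    frozenset({"IgM_lo", "IgM_hi"}): 4,
    frozenset({"IgM_only", "IgM_hi"}): 8,
    frozenset({"IgM_lo", "IgM_only"}): 1,
    frozenset({"IgM_lo", "IgM_only", "IgM_hi"}): 1,
}


@dataclass
class SimConfig:
    """Generator parameters; the seed fully determines the output."""

    n_donors: int = 3
    subsets: tuple[str, ...] = SUBSETS
    locus: str = "IGH"
    lineages_per_subset: int = 300
    v_genes: tuple[str, ...] = IGHV_GENES
    d_genes: tuple[str, ...] = IGHD_GENES
    j_genes: tuple[str, ...] = IGHJ_GENES
    v_usage: Mapping[str, np.ndarray] = field(default_factory=_default_v_usage)
    j_usage: Mapping[str, np.ndarray] = field(default_factory=_default_j_usage)
    shm: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_SHM))
    v_region_len: int = 300
    # lineage read counts: 1 + NegBin(size, p) — heavy-tailed, mass below 5
    size_nbinom_n: float = 0.45
    size_nbinom_p: float = 0.12
    # junction model
    cdr3_aa_mean: float = 15.0
    cdr3_aa_sd: float = 2.2
    cdr3_aa_min: int = 5
    cdr3_aa_max: int = 32
    n_geom_p: float = 0.25           # N1/N2 ~ Geometric(p) - 1 (mean 3)
    p_geom_p: float = 0.60           # P segments ~ min(Geometric(p) - 1, 3)
    productive_fraction: float = 0.90
    # planted sharing: pattern -> clonotypes per donor; planted lineages are
    # guaranteed at least plant_min_reads so the default lineage filter keeps
    # them
    sharing: Mapping[frozenset, int] = field(default_factory=lambda: dict(DEFAULT_SHARING))
    plant_min_reads: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ParameterError("n_donors must be >= 1")
        if not (0 < self.productive_fraction <= 1):
            raise ParameterError("productive_fraction must be in (0, 1]")
        for subset in self.subsets:
            for name, dist, ref in (
                ("v_usage", self.v_usage[subset], self.v_genes),
                ("j_usage", self.j_usage[subset], self.j_genes),
            ):
                dist = np.asarray(dist, dtype=float)
                if len(dist) != len(ref):
                    raise ParameterError(f"{name}[{subset}] length != gene list")
                if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
                    raise ParameterError(f"{name}[{subset}] is not a probability vector")
        for pattern, k in self.sharing.items():
            if not set(pattern) <= set(self.subsets):
                raise ParameterError(f"sharing pattern {set(pattern)} outside subsets")
            if len(pattern) < 2 or k < 0:
                raise ParameterError("sharing patterns need >= 2 subsets and count >= 0")


@dataclass
class GroundTruth:
    """Ledger covering every emitted row, plus the generating config."""

    records: pd.DataFrame   # sequence_id, donor_id, subset, v_call, j_call,
    # cdr3_nt, true_rate, n_mut, read_count, productive, planted_pattern
    config: SimConfig

    def planted_pattern_counts(self) -> dict[frozenset, int]:
        """Planted clonotype count per pattern, summed over donors."""
        planted = self.records[self.records["planted_pattern"] != ""]
        out: dict[frozenset, int] = {}
        for (_, _), grp in planted.groupby(["donor_id", "plant_id"]):
            pattern = frozenset(grp["subset"])
            out[pattern] = out.get(pattern, 0) + 1
        return out


def _draw_cdr3(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, str]:
    la = int(np.clip(round(rng.normal(cfg.cdr3_aa_mean, cfg.cdr3_aa_sd)),
                     cfg.cdr3_aa_min, cfg.cdr3_aa_max))
    codons = rng.choice(len(_CODONS), size=la)
    nt = "".join(_CODONS[i] for i in codons)
    aa = "".join(_CODON_AA[_CODONS[i]] for i in codons)
    return nt, aa


def _draw_junction_lengths(rng: np.random.Generator, cfg: SimConfig, nt_len: int):
    """N/P segment lengths partitioning the junction, clipped to fit.

    Reserves at least 3 nt each for the V tail and J head; remaining length is
    split between a D core and the drawn N/P segments (truncated in a fixed
    order if the draws exceed the budget).
    """
    n1 = int(rng.geometric(cfg.n_geom_p)) - 1
    n2 = int(rng.geometric(cfg.n_geom_p)) - 1
    ps = [min(int(rng.geometric(cfg.p_geom_p)) - 1, 3) for _ in range(4)]
    budget = max(nt_len - 6, 0)
    lengths = [n1, ps[0], ps[1], ps[2], ps[3], n2]  # n1, p3v, p5d, p3d, p5j, n2
    total = sum(lengths)
    while total > budget:
        for i in range(len(lengths)):
            if lengths[i] > 0 and total > budget:
                lengths[i] -= 1
                total -= 1
    n1, p3v, p5d, p3d, p5j, n2 = lengths
    return {"n1_len": n1, "n2_len": n2, "p3v_len": p3v,
            "p5d_len": p5d, "p3d_len": p3d, "p5j_len": p5j}


def _draw_size(rng: np.random.Generator, cfg: SimConfig, minimum: int = 1) -> int:
    while True:
        s = 1 + int(rng.negative_binomial(cfg.size_nbinom_n, cfg.size_nbinom_p))
        if s >= minimum:
            return s


def simulate_repertoire(config: SimConfig | None = None, seed: int | None = None
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate donor x subset rearrangement tables plus the truth ledger.

    One row is emitted per simulated lineage with ``duplicate_count`` equal to
    its read support; planted shared clonotypes carry identical
    ``(v_call, j_call, cdr3_nt)`` across the subsets of their pattern within
    one donor.  Deterministic for a fixed ``(config, seed)``.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    seq_counter = 0

    def emit(donor, subset, v, d, j, nt, aa, size, productive, rate, plant_id, pattern):
        nonlocal seq_counter
        seq_counter += 1
        sid = f"seq{seq_counter:07d}"
        L = cfg.v_region_len
        n_mut = int(rng.binomial(L, rate))
        v_ident = 100.0 * (1.0 - n_mut / L)
        n_mut_j = int(rng.binomial(50, rate))
        vj_ident = 100.0 * (1.0 - (n_mut + n_mut_j) / (L + 50))
        cdr3_nt, cdr3_aa = nt, aa
        if not productive:
            cdr3_nt = cdr3_nt + "ACGT"[int(rng.integers(4))]  # frameshift
            cdr3_aa = ""
        rows.append(
            {
                "sequence_id": sid,
                "donor_id": donor,
                "subset": subset,
                "locus": cfg.locus,
                "v_call": v,
                "d_call": d,
                "j_call": j,
                "cdr3_nt": cdr3_nt,
                "cdr3_aa": cdr3_aa,
                "productive": productive,
                "v_identity_pct": v_ident,
                "vj_germline_identity_pct": vj_ident,
                **_draw_junction_lengths(rng, cfg, len(cdr3_nt)),
                "duplicate_count": size,
            }
        )
        truth_rows.append(
            {
                "sequence_id": sid,
                "donor_id": donor,
                "subset": subset,
                "v_call": v,
                "j_call": j,
                "cdr3_nt": cdr3_nt,
                "true_rate": rate,
                "n_mut": n_mut,
                "read_count": size,
                "productive": productive,
                "plant_id": plant_id,
                "planted_pattern": pattern,
            }
        )

    for di in range(cfg.n_donors):
        donor = f"donor{di + 1}"
        # background lineages
        for subset in cfg.subsets:
            a, b = cfg.shm[subset]
            vprob = np.asarray(cfg.v_usage[subset], dtype=float)
            jprob = np.asarray(cfg.j_usage[subset], dtype=float)
            for _ in range(cfg.lineages_per_subset):
                v = cfg.v_genes[int(rng.choice(len(cfg.v_genes), p=vprob))]
                j = cfg.j_genes[int(rng.choice(len(cfg.j_genes), p=jprob))]
                d = cfg.d_genes[int(rng.integers(len(cfg.d_genes)))]
                nt, aa = _draw_cdr3(rng, cfg)
                size = _draw_size(rng, cfg)
                productive = bool(rng.random() < cfg.productive_fraction)
                rate = 0.0 if a == 0 else float(rng.beta(a, b))
                emit(donor, subset, v, d, j, nt, aa, size, productive, rate, "", "")
        # planted shared clonotypes (within this donor)
        plant_counter = 0
        for pattern in sorted(cfg.sharing, key=lambda p: sorted(p)):
            for _ in range(cfg.sharing[pattern]):
                plant_counter += 1
                pid = f"{donor}-plant{plant_counter:04d}"
                subset0 = sorted(pattern)[0]
                v = cfg.v_genes[int(rng.choice(len(cfg.v_genes),
                                               p=np.asarray(cfg.v_usage[subset0], float)))]
                j = cfg.j_genes[int(rng.choice(len(cfg.j_genes),
                                               p=np.asarray(cfg.j_usage[subset0], float)))]
                d = cfg.d_genes[int(rng.integers(len(cfg.d_genes)))]
                nt, aa = _draw_cdr3(rng, cfg)
                label = "+".join(sorted(pattern))
                for subset in sorted(pattern):
                    a, b = cfg.shm[subset]
                    rate = 0.0 if a == 0 else float(rng.beta(a, b))
                    size = _draw_size(rng, cfg, minimum=cfg.plant_min_reads)
                    emit(donor, subset, v, d, j, nt, aa, size, True, rate, pid, label)

    records = records_from_iterable(rows)
    records["v_family"] = records["v_call"].map(v_family_of)
    truth = GroundTruth(records=pd.DataFrame(truth_rows), config=cfg)
    return records, truth


# ---------------------------------------------------------------------------
# phenotype panel
# ---------------------------------------------------------------------------

_DEFAULT_MARKERS = (
    "CD1c", "CD69", "IL21R", "CD27", "MTG", "CD45RB",
    "CD5", "CD184", "CD23", "BAFFR", "CD38",
)


@dataclass
class PhenotypeConfig:
    """Marker-panel generator: log-normal MFI, logit-normal percent positive."""

    n_donors: int = 6
    subsets: tuple[str, ...] = SUBSETS
    markers: tuple[str, ...] = _DEFAULT_MARKERS
    # (subset, marker) -> (mean_mfi, mean_percent_positive); defaults drawn
    # once from the seed if not supplied
    means: Mapping[tuple[str, str], tuple[float, float]] | None = None
    mfi_sigma: float = 0.25          # log-scale SD
    pct_sigma: float = 0.40          # logit-scale SD
    seed: int = 0


def simulate_phenotype(config: PhenotypeConfig | None = None, seed: int | None = None
                       ) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[float, float]]]:
    """Generate a long (donor, subset, marker) panel and return its ledger.

    Returns the panel frame (columns donor, subset, marker, percent_positive,
    mfi) and the configured per-(subset, marker) means used to generate it.
    Zero dispersion reproduces the configured means exactly.
    """
    cfg = config or PhenotypeConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    means = dict(cfg.means) if cfg.means is not None else {}
    if not means:
        for subset in cfg.subsets:
            for marker in cfg.markers:
                means[(subset, marker)] = (
                    float(rng.uniform(200.0, 5000.0)),
                    float(rng.uniform(10.0, 90.0)),
                )

    rows = []
    for di in range(cfg.n_donors):
        donor = f"donor{di + 1}"
        for subset in cfg.subsets:
            for marker in cfg.markers:
                mean_mfi, mean_pct = means[(subset, marker)]
                if cfg.mfi_sigma > 0:
                    mfi = float(np.exp(rng.normal(np.log(mean_mfi), cfg.mfi_sigma)))
                else:
                    mfi = mean_mfi
                if cfg.pct_sigma > 0 and 0 < mean_pct < 100:
                    logit = np.log(mean_pct / (100.0 - mean_pct))
                    draw = rng.normal(logit, cfg.pct_sigma)
                    pct = float(100.0 / (1.0 + np.exp(-draw)))
                else:
                    pct = mean_pct
                rows.append(
                    {"donor": donor, "subset": subset, "marker": marker,
                     "percent_positive": pct, "mfi": mfi}
                )
    return pd.DataFrame(rows), means


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

def recovery_report(
    truth: GroundTruth,
    lineages: pd.DataFrame,
    pooled_sharing: SharingMatrix | None = None,
) -> pd.DataFrame:
    """Compare pipeline output against the generator's ledger.

    Rows cover V-gene usage frequencies per subset (configured probability vs
    recovered lineage frequency, with the binomial standard error at the
    recovered sample size), the mean SHM mutation percent per subset (Beta
    mean vs recovered mean, standard error of the mean), and — when a pooled
    within-donor sharing matrix is supplied — planted vs detected clonotype
    counts per sharing pattern (compared exactly).

    Raises :class:`ParameterError` when the lineages do not come from the
    ledgered run (unknown (donor, subset, V, J, CDR3) keys).
    """
    cfg = truth.config
    tkeys = set(
        map(tuple, truth.records[["donor_id", "subset", "v_call", "j_call", "cdr3_nt"]]
            .itertuples(index=False, name=None))
    )
    lkeys = set(
        map(tuple, lineages[["donor_id", "subset", "v_call", "j_call", "cdr3_nt"]]
            .itertuples(index=False, name=None))
    )
    if not lkeys <= tkeys:
        raise ParameterError("lineages do not match this ground-truth run")

    rows = []
    for subset in cfg.subsets:
        sub = lineages[lineages["subset"] == subset]
        n = len(sub)
        if n == 0:
            continue
        vprob = np.asarray(cfg.v_usage[subset], dtype=float)
        vc = sub["v_call"].value_counts()
        for gene, p in zip(cfg.v_genes, vprob):
            freq = vc.get(gene, 0) / n
            se = np.sqrt(p * (1.0 - p) / n)
            rows.append(
                {"quantity": "v_usage_freq", "subset": subset, "label": gene,
                 "configured": p, "recovered": freq, "n": n, "se": se,
                 "within_3se": bool(abs(freq - p) <= 3.0 * se)}
            )
        a, b = cfg.shm[subset]
        mut = mutation_percent(sub).to_numpy()
        mean_cfg = 100.0 * a / (a + b)
        sem = mut.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append(
            {"quantity": "shm_mean_pct", "subset": subset, "label": "",
             "configured": mean_cfg, "recovered": float(mut.mean()), "n": n,
             "se": sem, "within_3se": bool(abs(mut.mean() - mean_cfg) <= 3.0 * sem)}
        )

    if pooled_sharing is not None:
        planted = truth.planted_pattern_counts()
        patterns = set(planted) | set(pooled_sharing.pattern_counts)
        for pattern in sorted(patterns, key=lambda p: sorted(p)):
            want = planted.get(pattern, 0)
            got = pooled_sharing.pattern_counts.get(pattern, 0)
            rows.append(
                {"quantity": "sharing_count", "subset": "+".join(sorted(pattern)),
                 "label": "", "configured": want, "recovered": got, "n": want,
                 "se": 0.0, "within_3se": bool(want == got)}
            )
    return pd.DataFrame(rows)
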