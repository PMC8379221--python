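"""Synthetic cohorts with the statistical structure the analysis assumes.

Two layers are generated, both fully deterministic under a seed:

* A *sequence* layer — 3'UTRs carrying exactly one implanted canonical
  target site for a single focal miRNA (mirroring a single-transfection
  experiment), binding intervals whose distance to the site realizes a draw
  from a configurable distribution, and DMS count tracks whose in vivo
  openness increases with local RBP occupancy.
* A *statistical* layer — feature rows with confounders drawn from realistic
  marginal distributions, emulating a pooled multi-experiment dataset where
  TA and SPS vary across rows (within a single-miRNA cohort they are
  constants and cannot enter a regression).

Fold changes follow a linear model in the four confounders plus a monotone
saturating distance effect beta_d * exp(-d/tau) and Gaussian noise; beta_d < 0
encodes enhancement (more repression when binding is close). Non-target
transcripts receive pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import MicroRNA, RbsInterval, SiteMatch, scan_mts
from .features import local_au_content, seed_pairing_stability, target_abundance
from .io import IntervalRecord, Transcript, write_bed, write_fasta, write_table
from .structure import fold_mfe

#: hsa-let-7a-5p, the default focal miRNA of simulated transfections.
DEFAULT_MIRNA = MicroRNA(id="miR-sim-1", sequence="UGAGGUAGUAGGUUGUAUAGUU")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass
class DistanceDistribution:
    """Distribution of the MTS-to-nearest-RBS gap, the controlled variable.

    kind: "uniform" (0..d_max), "geometric" (success prob p), or
    "point_mass" (uniform choice among ``values``).
    """

    kind: str = "uniform"
    d_max: int = 300
    p: float = 0.02
    values: tuple[int, ...] = (0,)

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "uniform":
            return int(rng.integers(0, self.d_max + 1))
        if self.kind == "geometric":
            return int(rng.geometric(self.p) - 1)
        if self.kind == "point_mass":
            return int(rng.choice(self.values))
        raise ValueError(f"unknown distance distribution {self.kind!r}")


@dataclass
class EffectSizes:
    """Linear-model coefficients for the fold-change generator."""

    beta0: float = 0.0
    beta_au: float = -0.5
    beta_ta: float = 0.2
    beta_sps: float = 0.05
    beta_len: float = 0.1
    beta_d: float = -1.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 2000
    utr_length_mu: float = 6.0      # lognormal log-mean (median ~400 nt)
    utr_length_sigma: float = 0.5
    gc_fraction: float = 0.45
    target_fraction: float = 0.8    # remainder are no-site baselines
    n_rbps: int = 20
    rbs_per_utr_poisson_lambda: float = 1.5
    rbs_width: int = 30
    distance_distribution: DistanceDistribution = field(
        default_factory=DistanceDistribution)
    p_overlap: float = 0.15         # probability the nearest RBS overlaps the MTS
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    distance_decay_scale: float = 50.0   # tau, nt
    noise_sigma: float = 1.0
    dms_openness_gain: float = 1.0
    dms_depth: float = 50.0         # expected counts at a fully open A/C position
    library_size: int = 1_000_000
    n_replicates: int = 2
    expression_mu: float = 2.0      # lognormal log-mean of TPM-like expression
    expression_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0,1)")
        if self.distance_decay_scale <= 0:
            raise ValueError("tau must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.p_overlap <= 1:
            raise ValueError("p_overlap must be in [0,1]")


@dataclass
class GroundTruth:
    """Implanted truth for every transcript, for round-trip verification."""

    mirna: MicroRNA
    sites: dict[str, SiteMatch]
    d_true: dict[str, int]
    overlapped: dict[str, bool]
    nearest_rbp: dict[str, str]
    table: pd.DataFrame  # per-transcript truth incl. confounders and noiseless fc


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGU"), size=length, p=probs))


def _destroy_spurious_sites(
    seq: list[str], keep: tuple[int, int], mirna: MicroRNA,
    rng: np.random.Generator, max_iter: int = 100,
) -> bool:
    """Substitute single bases until the kept window is the only match."""
    for _ in range(max_iter):
        matches = scan_mts("".join(seq), mirna)
        spurious = [m for m in matches if (m.start, m.end) != keep]
        if not spurious:
            return True
        for m in spurious:
            # mutate a base in the match that lies outside the kept window
            positions = [p for p in range(m.start, m.end)
                         if not keep[0] <= p < keep[1]]
            if not positions:
                continue
            p = int(rng.choice(positions))
            seq[p] = str(rng.choice([b for b in "ACGU" if b != seq[p]]))
    return False


def generate_transcriptome(
    config: SimulationConfig, mirna: MicroRNA = DEFAULT_MIRNA
) -> tuple[list[Transcript], GroundTruth]:
    """Generate 3'UTRs, each target carrying exactly one implanted site.

    UTR lengths are lognormal; the implanted site's type is uniform over the
    three canonical types; every spontaneous seed match for the focal miRNA
    is destroyed by single-base substitution (so sequences stay valid for
    folding). Expression is lognormal. Non-target transcripts (the remaining
    ``1 - target_fraction``) carry no site at all.
    """
    rng = np.random.default_rng(config.seed)
    patterns = {"8mer": mirna.site_8mer, "7mer-m8": mirna.site_7mer_m8,
                "7mer-A1": mirna.site_7mer_a1}
    transcripts: list[Transcript] = []
    sites: dict[str, SiteMatch] = {}
    truth_rows = []
    n_targets = int(round(config.n_transcripts * config.target_fraction))
    margin = config.rbs_width + 2  # room for an RBS on either flank
    for i in range(config.n_transcripts):
        tx_id = f"tx{i:05d}"
        is_target = i < n_targets
        for attempt in range(101):
            if attempt == 100:
                raise RuntimeError(f"{tx_id}: could not host a site in 100 tries")
            length = int(np.exp(rng.normal(config.utr_length_mu,
                                           config.utr_length_sigma)))
            site_type = str(rng.choice(SITE_TYPES))
            pat = patterns[site_type]
            if not is_target:
                if length < 30:
                    continue
                seq = _random_seq(rng, length, config.gc_fraction)
                if _destroy_spurious_sites(seq, (-1, -1), mirna, rng):
                    break
                continue
            if length < len(pat) + 2 * margin:
                continue
            seq = _random_seq(rng, length, config.gc_fraction)
            start = int(rng.integers(margin, length - len(pat) - margin + 1))
            seq[start : start + len(pat)] = list(pat)
            if _destroy_spurious_sites(seq, (start, start + len(pat)), mirna, rng):
                break
        utr = "".join(seq)
        expression = float(np.exp(rng.normal(config.expression_mu,
                                             config.expression_sigma)))
        transcripts.append(Transcript(id=tx_id, utr_seq=utr, expression=expression))
        if is_target:
            site = SiteMatch(transcript_id=tx_id, start=start,
                             end=start + len(pat), site_type=site_type,
                             mirna_id=mirna.id)
            sites[tx_id] = site
            truth_rows.append({
                "transcript": tx_id, "site_type": site_type,
                "site_start": site.start, "site_end": site.end,
                "local_au": local_au_content(utr, site),
                "log10_len": float(np.log10(len(utr))),
                "expression": expression,
            })
        else:
            truth_rows.append({
                "transcript": tx_id, "site_type": "none",
                "site_start": -1, "site_end": -1,
                "local_au": np.nan,
                "log10_len": float(np.log10(len(utr))),
                "expression": expression,
            })
    table = pd.DataFrame(truth_rows)
    ta = target_abundance(mirna, transcripts)
    table["ta"] = ta
    table["sps"] = seed_pairing_stability(mirna)
    return transcripts, GroundTruth(mirna=mirna, sites=sites, d_true={},
                                    overlapped={}, nearest_rbp={}, table=table)


def implant_rbs(
    transcripts: Sequence[Transcript],
    ground_truth: GroundTruth,
    config: SimulationConfig,
) -> list[RbsInterval]:
    """Place binding intervals so the nearest one realizes a drawn distance.

    Per target transcript, one RBP (chosen at random) carries the nearest
    interval at gap d drawn from the distance distribution; with probability
    ``p_overlap`` the nearest interval instead straddles the site (d = 0,
    overlapped). Each of the other RBPs contributes a Poisson number of
    intervals, re-drawn if they land closer than the realized d. Tiers are
    stringent with probability 0.5; replicate support 1 or 2 equally.
    """
    rng = np.random.default_rng(config.seed + 1)
    width = config.rbs_width
    out: list[RbsInterval] = []
    rbp_ids = [f"RBP{r:03d}" for r in range(config.n_rbps)]
    for tx in transcripts:
        site = ground_truth.sites.get(tx.id)
        if site is None:
            continue
        L = len(tx)
        make_overlap = rng.random() < config.p_overlap
        for _ in range(101):
            d = 0 if make_overlap else config.distance_distribution.draw(rng)
            placements = []
            if make_overlap:
                lo = max(0, site.start - width + 1)
                hi = min(L - width, site.end - 1)
                if lo <= hi:
                    placements.append(int(rng.integers(lo, hi + 1)))
            else:
                right = site.end + d
                if right + width <= L:
                    placements.append(right)
                left = site.start - d - width
                if left >= 0:
                    placements.append(left)
            if placements:
                near_start = int(rng.choice(placements))
                break
        else:
            raise RuntimeError(f"{tx.id}: could not place nearest RBS")
        near_rbp = str(rng.choice(rbp_ids))
        tier = "stringent" if rng.random() < 0.5 else "lenient"
        out.append(RbsInterval(near_rbp, tx.id, near_start, near_start + width,
                               stringency=tier,
                               support=int(rng.integers(1, 3))))
        realized_gap = max(0, max(site.start, near_start)
                           - min(site.end, near_start + width))
        overlapped = near_start < site.end and site.start < near_start + width
        ground_truth.d_true[tx.id] = 0 if overlapped else realized_gap
        ground_truth.overlapped[tx.id] = overlapped
        ground_truth.nearest_rbp[tx.id] = near_rbp
        floor = ground_truth.d_true[tx.id]
        for rbp in rbp_ids:
            n_extra = int(rng.poisson(config.rbs_per_utr_poisson_lambda))
            for _ in range(n_extra):
                for _try in range(100):
                    s = int(rng.integers(0, max(1, L - width)))
                    gap = max(0, max(site.start, s) - min(site.end, s + width))
                    ov = s < site.end and site.start < s + width
                    if (gap > floor) or (gap == floor and not ov and not make_overlap
                                         and gap > 0):
                        out.append(RbsInterval(
                            rbp, tx.id, s, s + width,
                            stringency="stringent" if rng.random() < 0.5 else "lenient",
                            support=int(rng.integers(1, 3))))
                        break
    return out


def sample_feature_rows(
    n: int,
    config: SimulationConfig,
    confounder_d_corr: float = 0.0,
    rbp_id: str = "RBP000",
) -> pd.DataFrame:
    """Statistical-layer cohort: feature rows with varying confounders.

    Emulates a pooled multi-experiment dataset: local AU ~ Beta(2,2),
    TA ~ N(2.5, 0.4), SPS ~ N(-14, 2), log10 length ~ N(2.8, 0.25), distance
    from the configured distribution with an overlapped point mass. With
    ``confounder_d_corr`` > 0 each confounder is deliberately tilted along
    the (standardized) distance, creating the confounding the correction
    machinery must remove. Site types are uniform.
    """
    rng = np.random.default_rng(config.seed + 2)
    overlapped = rng.random(n) < config.p_overlap
    d = np.array([0 if o else config.distance_distribution.draw(rng)
                  for o in overlapped], dtype=float)
    df = pd.DataFrame({
        "transcript": [f"tx{i:05d}" for i in range(n)],
        "mirna": DEFAULT_MIRNA.id,
        "rbp": rbp_id,
        "site_type": rng.choice(SITE_TYPES, size=n),
        "d": d,
        "overlapped": overlapped,
        "local_au": rng.beta(2, 2, size=n),
        "ta": rng.normal(2.5, 0.4, size=n),
        "sps": rng.normal(-14.0, 2.0, size=n),
        "log10_len": rng.normal(2.8, 0.25, size=n),
    })
    if confounder_d_corr:
        zd = (d - d.mean()) / (d.std() or 1.0)
        for col, scale in (("local_au", 0.15), ("ta", 0.4),
                           ("sps", 2.0), ("log10_len", 0.25)):
            df[col] = df[col] + confounder_d_corr * zd * scale
        df["local_au"] = df["local_au"].clip(0, 1)
    return df


def simulate_fold_changes(
    feature_rows: pd.DataFrame,
    effect_sizes: EffectSizes,
    tau: float,
    noise_sigma: float,
    seed: int,
) -> pd.DataFrame:
    """Attach log2 fold changes: linear confounder model + distance effect.

    log2fc = b0 + b_AU*AU + b_TA*TA + b_SPS*SPS + b_len*log10len
             + b_d*exp(-d/tau) + N(0, sigma^2).
    Rows with missing d (no RBS / non-target) receive pure noise. The
    noiseless value is kept in ``log2fc_true``.
    """
    rng = np.random.default_rng(seed)
    df = feature_rows.copy()
    e = effect_sizes
    d = df["d"].to_numpy(float)
    base = (e.beta0
            + e.beta_au * df["local_au"].to_numpy(float)
            + e.beta_ta * df["ta"].to_numpy(float)
            + e.beta_sps * df["sps"].to_numpy(float)
            + e.beta_len * df["log10_len"].to_numpy(float))
    with np.errstate(invalid="ignore"):
        dist_effect = e.beta_d * np.exp(-d / tau)
    true = np.where(np.isnan(d), 0.0, base + np.nan_to_num(dist_effect))
    df["log2fc_true"] = true
    df["log2fc"] = true + rng.normal(0.0, noise_sigma, size=len(df))
    return df


def ground_truth_feature_table(
    transcripts: Sequence[Transcript],
    ground_truth: GroundTruth,
) -> pd.DataFrame:
    """Feature rows from sequence-layer ground truth (target transcripts)."""
    rows = []
    for tx in transcripts:
        if tx.id not in ground_truth.sites:
            continue
        t = ground_truth.table.set_index("transcript").loc[tx.id]
        rows.append({
            "transcript": tx.id,
            "mirna": ground_truth.mirna.id,
            "site_type": ground_truth.sites[tx.id].site_type,
            "d": float(ground_truth.d_true[tx.id]),
            "overlapped": ground_truth.overlapped[tx.id],
            "local_au": float(t["local_au"]),
            "ta": float(t["ta"]),
            "sps": float(t["sps"]),
            "log10_len": float(t["log10_len"]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMS counts
# ---------------------------------------------------------------------------

DMS_CONDITIONS = ("in_vivo", "in_vitro", "denatured", "dms_minus")


def _paired_indicator(seq: str, chunk: int = 100) -> np.ndarray:
    """Per-position paired flag from folding the sequence in chunks."""
    paired = np.zeros(len(seq), dtype=bool)
    for s in range(0, len(seq), chunk):
        sub = seq[s : s + chunk]
        _, struct = fold_mfe(sub, length_cap=chunk)
        for i, ch in enumerate(struct):
            paired[s + i] = ch != "."
    return paired


def occupancy_profile(length: int, rbs: Sequence[RbsInterval]) -> np.ndarray:
    """Per-position RBP occupancy: stringent RBSs weigh 1, lenient 0.5,
    summed over overlapping intervals and capped at 1."""
    occ = np.zeros(length)
    for iv in rbs:
        w = 1.0 if iv.stringency == "stringent" else 0.5
        occ[iv.start : min(iv.end, length)] += w
    return np.minimum(occ, 1.0)


def simulate_dms_counts(
    transcripts: Sequence[Transcript],
    rbs: Sequence[RbsInterval],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Poisson DMS count tracks for the four conditions.

    A/C positions only carry signal (G/U counts are always zero). The
    denatured rate is uniform; the in vitro rate reflects a paired indicator
    from folding (paired positions are 4x less reactive); the in vivo rate is
    the in vitro rate times (1 + gain * occupancy); the DMS(-) background is
    flat and low. Expected counts at a fully open position equal
    ``dms_depth``. Long format: transcript, pos, condition, replicate, count.
    """
    rng = np.random.default_rng(config.seed + 3)
    rbs_by_tx: dict[str, list[RbsInterval]] = {}
    for iv in rbs:
        rbs_by_tx.setdefault(iv.transcript_id, []).append(iv)
    frames = []
    for tx in transcripts:
        seq = tx.utr_seq
        n = len(seq)
        ac = np.array([b in "AC" for b in seq])
        paired = _paired_indicator(seq)
        occ = occupancy_profile(n, rbs_by_tx.get(tx.id, ()))
        vitro_rate = np.where(paired, 0.25, 1.0) * ac
        rates = {
            "denatured": 1.0 * ac,
            "in_vitro": vitro_rate,
            "in_vivo": vitro_rate * (1.0 + config.dms_openness_gain * occ),
            "dms_minus": 0.05 * ac,
        }
        pos = np.arange(n)
        for cond in DMS_CONDITIONS:
            lam = rates[cond] * config.dms_depth
            for rep in range(1, config.n_replicates + 1):
                counts = rng.poisson(lam)
                frames.append(pd.DataFrame({
                    "transcript": tx.id, "pos": pos, "condition": cond,
                    "replicate": rep, "count": counts,
                }))
    return pd.concat(frames, ignore_index=True)


def dms_levels_from_counts(
    counts: pd.DataFrame, transcripts: Sequence[Transcript],
    library_size: float,
) -> dict[tuple[str, str], np.ndarray]:
    """(transcript, condition) -> per-position DMS level (replicate-mean RPM)."""
    from .structure import dms_level, rpm_normalize

    lengths = {t.id: len(t) for t in transcripts}
    out: dict[tuple[str, str], np.ndarray] = {}
    for (tx, cond), grp in counts.groupby(["transcript", "condition"]):
        reps = []
        for _, rep_grp in grp.groupby("replicate"):
            vec = np.zeros(lengths[tx])
            vec[rep_grp["pos"].to_numpy()] = rep_grp["count"].to_numpy(float)
            reps.append(rpm_normalize(vec, library_size))
        out[(tx, cond)] = dms_level(reps)
    return out


def write_cohort(
    out_dir: str | Path,
    transcripts: Sequence[Transcript],
    ground_truth: GroundTruth,
    rbs: Sequence[RbsInterval],
    fold_changes: pd.DataFrame,
    dms_counts: pd.DataFrame | None = None,
) -> None:
    """Write the full simulated cohort as the pipeline's standard files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(transcripts, out / "utrs.fasta")
    write_fasta([Transcript(ground_truth.mirna.id, ground_truth.mirna.sequence)],
                out / "mirna.fasta")
    write_bed([IntervalRecord(iv.transcript_id, iv.start, iv.end,
                              f"{iv.rbp_id}:{iv.stringency}", iv.support)
               for iv in rbs], out / "rbs.bed")
    write_table(pd.DataFrame({
        "transcript": [t.id for t in transcripts],
        "expression": [t.expression for t in transcripts],
    }), out / "expression.tsv")
    write_table(fold_changes[["transcript", "mirna", "log2fc"]],
                out / "fold_changes.tsv")
    write_table(ground_truth.table.assign(
        d=[ground_truth.d_true.get(t, np.nan)
           for t in ground_truth.table["transcript"]],
        overlapped=[ground_truth.overlapped.get(t, False)
                    for t in ground_truth.table["transcript"]],
    ), out / "ground_truth.tsv")
    if dms_counts is not None:
        write_table(dms_counts, out / "dms_counts.tsv")
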