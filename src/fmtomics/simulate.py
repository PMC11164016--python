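"""Trial-like multi-omics data generator with known ground truth.

Emulates the structure of a randomized 2:1 FMT-vs-placebo trial in
allogeneic HCT: 74 patients, 4 stool donors, longitudinal stool timepoints
(baseline, pre-dose, day 10, day 28, 9 months) with realistic per-timepoint
missingness, genus compositions drawn from a mixture of latent
subcommunities (LDA-style topics) whose weights depend on arm and timepoint,
an ASV-level engraftment process that copies donor-specific variants of one
planted genus into post-FMT recipients (coupling donor similarity with that
genus's abundance), a binary aGVHD outcome driven by the log ratio of the planted
genus to designated reference genera plus a prophylaxis covariate, and a two-batch serum metabolome
with anchor samples, zero inflation, collinear blocks and one planted
protective metabolite.

Every generator is deterministic given the config seed; each stage draws
from its own seeded stream so toggling one stage cannot shift another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .metabolome import MetaboliteMatrix
from .prep import CountTable, SampleMeta

DEFAULT_ANCHORS = {
    1: ["Alistipes", "Faecalibacterium", "Blautia"],
    2: ["Bacteroides", "Parabacteroides", "Akkermansia"],
    3: ["Streptococcus", "Veillonella", "Escherichia-Shigella"],
}

# per-timepoint sample retention probabilities (tuned to the trial's reported
# per-timepoint sample counts over 74 patients)
STOOL_RETENTION = {"baseline": 0.96, "pre": 0.80, "post10": 0.40, "post28": 0.62, "late": 0.49}
SERUM_RETENTION = {"baseline": 0.84, "pre": 0.80, "post28": 0.72, "late": 0.38}


@dataclass
class SimConfig:
    n_patients: int = 74
    arm_ratio: tuple[int, int] = (2, 1)  # FMT : placebo
    n_donors: int = 4
    timepoints: tuple[str, ...] = ("baseline", "pre", "post10", "post28", "late")
    n_genera: int = 170
    n_asvs_per_genus: tuple[int, int] = (2, 4)
    n_topics_true: int = 3
    topic_anchor_genera: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ANCHORS.items()})
    anchor_mass: float = 0.75
    planted_topic_share: float = 0.08
    planted_genus: str = "Faecalibacterium"
    beta_outcome: float = 1.5  # log-odds per unit of the planted log-ratio score
    n_reference_genera: int = 2
    gamma_prophylaxis: float = 0.5
    event_rate: float = 0.35
    ptcy_rate: float = 0.554
    engraftment_rate: float = 0.5
    engraft_boost: float = 0.75
    n_donor_planted_asvs: int = 24
    n_donor_pool_asvs: int = 2
    n_recipient_planted_asvs: int = 3
    recipient_planted_pool: int = 20
    theta_concentration: float = 60.0
    genus_dispersion: float = 400.0
    depth_range: tuple[int, int] = (5_000, 50_000)
    frac_shallow: float = 0.03
    n_metabolites: int = 250
    n_anchor_samples: int = 18
    frac_collinear: float = 0.3
    collinear_block_size: int = 5
    zero_rate: float = 0.05
    frac_poorly_detected: float = 0.3
    poor_zero_rate: float = 0.45
    batch_scale_range: tuple[float, float] = (0.5, 2.0)
    protective_beta: float = 1.0
    stool_retention: dict = field(default_factory=lambda: dict(STOOL_RETENTION))
    serum_retention: dict = field(default_factory=lambda: dict(SERUM_RETENTION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        r1, r2 = self.arm_ratio
        if r1 <= 0 or r2 <= 0:
            raise ValueError("arm_ratio parts must be positive")
        if self.n_donors <= 0 or self.n_genera <= 0 or self.n_metabolites <= 0:
            raise ValueError("counts must be positive")
        anchors_with_planted = [
            t for t, gl in self.topic_anchor_genera.items() if self.planted_genus in gl
        ]
        if len(anchors_with_planted) != 1:
            raise ValueError("planted_genus must be an anchor of exactly one topic")
        for prob in (
            self.engraftment_rate, self.event_rate, self.zero_rate,
            self.frac_collinear, self.frac_shallow, self.ptcy_rate,
            self.poor_zero_rate, self.frac_poorly_detected,
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.topic_anchor_genera) != self.n_topics_true:
            raise ValueError("topic_anchor_genera must define every topic")

    @property
    def n_fmt(self) -> int:
        r1, r2 = self.arm_ratio
        return int(round(self.n_patients * r1 / (r1 + r2)))

    @property
    def n_placebo(self) -> int:
        return self.n_patients - self.n_fmt


@dataclass
class GroundTruth:
    true_topic_term: Optional[pd.DataFrame] = None
    true_sample_topics: Optional[pd.DataFrame] = None
    outcome_labels: Optional[pd.Series] = None
    planted_genus: Optional[str] = None
    planted_metabolite: Optional[str] = None
    donor_asv_sets: dict = field(default_factory=dict)
    engrafted_counts: dict = field(default_factory=dict)
    batch_factors: Optional[pd.Series] = None
    collinear_blocks: list = field(default_factory=list)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def generate_cohort(config: SimConfig) -> SampleMeta:
    """Patient/donor metadata: randomized arm allocation, donor assignment
    for the FMT arm, prophylaxis labels, and per-timepoint sample presence."""
    rng = _rng(config, 0)
    n = config.n_patients
    pids = [f"P{i + 1:03d}" for i in range(n)]
    arm = np.array(["FMT"] * config.n_fmt + ["placebo"] * config.n_placebo, dtype=object)
    rng.shuffle(arm)
    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    donor_of = {
        pid: (donors[rng.integers(config.n_donors)] if a == "FMT" else None)
        for pid, a in zip(pids, arm)
    }
    ptcy = rng.random(n) < config.ptcy_rate
    rows = []
    for did in donors:
        rows.append(
            {
                "sample_id": f"{did}_donor",
                "patient_id": did,
                "role": "donor",
                "arm": pd.NA,
                "timepoint": "donor",
                "donor_id": pd.NA,
                "outcome": pd.NA,
                "prophylaxis": pd.NA,
            }
        )
    for pid, a, pt in zip(pids, arm, ptcy):
        for tp in config.timepoints:
            if rng.random() >= config.stool_retention.get(tp, 1.0):
                continue
            rows.append(
                {
                    "sample_id": f"{pid}_{tp}",
                    "patient_id": pid,
                    "role": "patient",
                    "arm": a,
                    "timepoint": tp,
                    "donor_id": donor_of[pid],
                    "outcome": pd.NA,
                    "prophylaxis": "PTCy" if pt else "other",
                }
            )
    tbl = pd.DataFrame(rows).set_index("sample_id")
    return SampleMeta(tbl)


def _topic_means(
    config: SimConfig,
    role: str,
    arm,
    timepoint: str,
    base_topic: int = 0,
    dys_topic: int | None = None,
) -> np.ndarray:
    """Group-dependent mean topic weights.

    Donors and post-FMT samples are enriched in the first (commensal) topic;
    pre-dose and post-placebo samples in the patient's dysbiosis topic
    (``dys_topic``, one of the non-commensal topics — so every topic
    dominates some samples, as in the trial's sample groups); baseline
    samples lean toward a per-patient ``base_topic`` without obvious
    predilection."""
    k = config.n_topics_true
    m = np.ones(k)
    if dys_topic is None:
        dys_topic = k - 1
    if role == "donor":
        m[0] *= 10.0
        m[-1] *= 0.3
    elif timepoint == "baseline":
        m[base_topic] *= 3.0
    elif timepoint == "pre":
        m[1:] *= 0.4  # damp the other dysbiosis topics
        m[dys_topic] = 5.0
        m[0] *= 0.5
    elif timepoint in ("post10", "post28"):
        if arm == "FMT":
            m[0] *= 6.0
        else:
            m[1:] *= 0.4
            m[dys_topic] = 4.0
            m[0] *= 0.6
    elif timepoint == "late":
        m[0] *= 4.0 if arm == "FMT" else 1.8
    return m / m.sum()


def _build_topic_term(config: SimConfig, rng) -> tuple[pd.DataFrame, list[str]]:
    anchors = config.topic_anchor_genera
    anchor_list = [g for t in sorted(anchors) for g in anchors[t]]
    n_fill = config.n_genera - len(anchor_list)
    if n_fill < 0:
        raise ValueError("n_genera smaller than total anchor count")
    fillers = [f"Genus{i + 1:03d}" for i in range(n_fill)]
    genera = anchor_list + fillers
    k = config.n_topics_true
    beta = np.zeros((k, len(genera)))
    for ti, t in enumerate(sorted(anchors)):
        gl = anchors[t]
        shares = np.linspace(1.5, 1.0, len(gl))
        shares = shares / shares.sum() * config.anchor_mass
        # the planted genus gets a deliberately small topic share: its
        # outcome-relevant variation comes from the engraftment process, not
        # from the shared subcommunity factor, so it is not interchangeable
        # with its fellow anchors in regression
        if config.planted_genus in gl:
            others = [g for g in gl if g != config.planted_genus]
            rest = config.anchor_mass - config.planted_topic_share
            osh = np.linspace(1.5, 1.0, len(others))
            osh = osh / osh.sum() * rest
            beta[ti, genera.index(config.planted_genus)] = config.planted_topic_share
            for g, s in zip(others, osh):
                beta[ti, genera.index(g)] = s
        else:
            for g, s in zip(gl, shares):
                beta[ti, genera.index(g)] = s
        bg = rng.dirichlet(np.full(n_fill, 0.3))
        # reference genera are stable "housekeeping" background members: a
        # fixed, non-negligible share of every topic's background mass, so
        # log-ratios against them are well measured
        n_ref = min(config.n_reference_genera, n_fill)
        ref_share = 0.08
        bg[:n_ref] = ref_share
        bg[n_ref:] = bg[n_ref:] / bg[n_ref:].sum() * (1 - n_ref * ref_share)
        beta[ti, len(anchor_list):] = (1 - config.anchor_mass) * bg
    tt = pd.DataFrame(beta, index=[f"topic{t}" for t in sorted(anchors)], columns=genera)
    return tt, genera


def generate_microbiome(
    meta: SampleMeta, config: SimConfig
) -> tuple[CountTable, GroundTruth]:
    """ASV count table for every sample in ``meta``.

    Genus composition is theta @ topic_term with sample-level Dirichlet
    variation in theta; ASV counts are multinomial at a log-uniform
    sequencing depth. Post-FMT samples of FMT patients additionally carry
    donor-specific planted-genus ASVs (engrafted once per patient with
    probability ``engraftment_rate`` per donor ASV), which boosts the
    planted genus's abundance in proportion to the engrafted fraction.
    """
    rng = _rng(config, 1)
    tt, genera = _build_topic_term(config, rng)
    k = config.n_topics_true
    tbl = meta.table
    planted = config.planted_genus

    # ASV layout
    asv_cols: list[str] = []
    genus_of: dict[str, str] = {}
    asv_weights: dict[str, np.ndarray] = {}
    genus_asvs: dict[str, list[str]] = {}
    lo, hi = config.n_asvs_per_genus
    for g in genera:
        if g == planted:
            continue
        n_asv = int(rng.integers(lo, hi + 1))
        ids = [f"{g}_ASV{i + 1}" for i in range(n_asv)]
        genus_asvs[g] = ids
        asv_weights[g] = rng.dirichlet(np.full(n_asv, 5.0))
        for a in ids:
            genus_of[a] = g
        asv_cols.extend(ids)
    # planted genus: donor-unique ASVs + a shared recipient pool
    donors = sorted(tbl.loc[tbl["role"] == "donor", "patient_id"])
    pool = [f"{planted}_recip_ASV{i + 1}" for i in range(config.recipient_planted_pool)]
    donor_unique = {
        d: [f"{planted}_{d}_ASV{i + 1}" for i in range(config.n_donor_planted_asvs)]
        for d in donors
    }
    # donors also carry a few pool variants, so donor/recipient sharing is not
    # exactly zero even without engraftment
    donor_asv_sets = {
        d: donor_unique[d]
        + list(rng.choice(pool, size=config.n_donor_pool_asvs, replace=False))
        for d in donors
    }
    planted_cols = [a for d in donors for a in donor_unique[d]] + pool
    for a in planted_cols:
        genus_of[a] = planted
    asv_cols.extend(planted_cols)
    genus_asvs[planted] = planted_cols

    patient_own = {}
    patient_engrafted = {}
    for pid in tbl.loc[tbl["role"] == "patient", "patient_id"].unique():
        patient_own[pid] = list(rng.choice(pool, size=config.n_recipient_planted_asvs, replace=False))
    for pid, grp in tbl[tbl["role"] == "patient"].groupby("patient_id", sort=True):
        did = grp["donor_id"].dropna().unique()
        if len(did) and grp["arm"].iloc[0] == "FMT":
            dset = donor_asv_sets[did[0]]
            hits = rng.random(len(dset)) < config.engraftment_rate
            patient_engrafted[pid] = [a for a, h in zip(dset, hits) if h]

    n_donor_total = config.n_donor_planted_asvs + config.n_donor_pool_asvs
    donor_weights = {d: rng.dirichlet(np.full(n_donor_total, 8.0)) for d in donors}

    # per-patient latent states: which topic their baseline leans toward, and
    # which non-commensal topic dominates their dysbiotic samples
    patient_ids = tbl.loc[tbl["role"] == "patient", "patient_id"].unique()
    base_topic = {pid: int(rng.integers(0, k)) for pid in sorted(patient_ids)}
    dys_topic = {pid: int(rng.integers(1, k)) if k > 1 else 0 for pid in sorted(patient_ids)}

    counts = np.zeros((len(tbl), len(asv_cols)), dtype=int)
    col_idx = {a: i for i, a in enumerate(asv_cols)}
    genus_idx = {g: i for i, g in enumerate(genera)}
    thetas = np.zeros((len(tbl), k))
    lo_d, hi_d = config.depth_range
    for ri, (sid, row) in enumerate(tbl.iterrows()):
        means = _topic_means(
            config, row["role"], row["arm"], row["timepoint"],
            base_topic=base_topic.get(row["patient_id"], 0),
            dys_topic=dys_topic.get(row["patient_id"]),
        )
        theta = rng.dirichlet(config.theta_concentration * means)
        thetas[ri] = theta
        gp = theta @ tt.to_numpy()
        # engraftment boost of the planted genus for post-FMT samples
        pid = row["patient_id"]
        engrafted = []
        if (
            row["role"] == "patient"
            and row["arm"] == "FMT"
            and row["timepoint"] in ("post10", "post28", "late")
        ):
            engrafted = patient_engrafted.get(pid, [])
            boost = config.engraft_boost * len(engrafted) / n_donor_total
            gp = gp.copy()
            gp[genus_idx[planted]] += boost
            gp = gp / gp.sum()
        # engrafted share of the planted genus, fixed before overdispersion
        engrafted_frac = 0.0
        if engrafted:
            pg_planted = gp[genus_idx[planted]]
            engrafted_frac = min(boost / (1.0 + boost), pg_planted) / pg_planted
        # Dirichlet-multinomial overdispersion: per-genus idiosyncratic
        # variation around the topic-mixture composition. The planted genus
        # keeps its exact share - its abundance is modeled explicitly through
        # the engraftment process.
        pi = genus_idx[planted]
        others = np.ones(len(gp), dtype=bool)
        others[pi] = False
        sub = gp[others] / gp[others].sum()
        noisy = rng.dirichlet(np.maximum(config.genus_dispersion * sub, 1e-3))
        noisy = np.maximum(noisy, 1e-12)
        gp = gp.copy()
        gp[others] = (1.0 - gp[pi]) * noisy / noisy.sum()
        # expand genus probabilities to ASV probabilities
        p_asv = np.zeros(len(asv_cols))
        for g in genera:
            pg = gp[genus_idx[g]]
            if g == planted:
                if row["role"] == "donor":
                    own = donor_asv_sets[pid]
                    w = donor_weights[pid]
                else:
                    own = patient_own[pid]
                    w = np.full(len(own), 1.0 / len(own))
                if engrafted:
                    boost_mass = engrafted_frac * pg
                    own_mass = pg - boost_mass
                    for a, wi in zip(own, w):
                        p_asv[col_idx[a]] = own_mass * wi
                    for a in engrafted:
                        p_asv[col_idx[a]] = boost_mass / len(engrafted)
                else:
                    for a, wi in zip(own, w):
                        p_asv[col_idx[a]] = pg * wi
            else:
                for a, wi in zip(genus_asvs[g], asv_weights[g]):
                    p_asv[col_idx[a]] = pg * wi
        p_asv = p_asv / p_asv.sum()
        if rng.random() < config.frac_shallow:
            depth = int(rng.integers(200, 1000))
        else:
            depth = int(np.exp(rng.uniform(np.log(lo_d), np.log(hi_d))))
        counts[ri] = rng.multinomial(depth, p_asv)

    taxonomy = pd.DataFrame(
        {
            "family": [f"{genus_of[a]}aceae" for a in asv_cols],
            "genus": [genus_of[a] for a in asv_cols],
        },
        index=pd.Index(asv_cols, name="asv_id"),
    )
    table = CountTable(
        pd.DataFrame(counts, index=tbl.index, columns=asv_cols), taxonomy
    )
    truth = GroundTruth(
        true_topic_term=tt,
        true_sample_topics=pd.DataFrame(thetas, index=tbl.index, columns=tt.index),
        planted_genus=planted,
        donor_asv_sets={d: set(v) for d, v in donor_asv_sets.items()},
        engrafted_counts={p: len(v) for p, v in patient_engrafted.items()},
    )
    return table, truth


def reference_genera(config: SimConfig) -> list[str]:
    """The designated reference genera of the generative log-ratio risk
    score (the first ``n_reference_genera`` background genera)."""
    return [f"Genus{i + 1:03d}" for i in range(config.n_reference_genera)]


def _early_post_risk_score(meta: SampleMeta, counts: CountTable, config: SimConfig):
    """Per-patient log-ratio risk score at the early-post timepoint (day-28
    sample preferred, else day-10): log relative planted-genus abundance
    minus the mean log relative abundance of the reference genera.

    A log-ratio contrast is exactly representable as a sparse zero-sum
    coefficient vector (+1 on the planted genus, -1/r on each reference), so
    the planted signal is recoverable by sparse compositional regression.
    """
    from .prep import collapse_to_genus

    genus = collapse_to_genus(counts, prevalence_min=0.0)
    arr = genus.counts.to_numpy(dtype=float) + 0.5
    logp = pd.DataFrame(
        np.log(arr / arr.sum(axis=1, keepdims=True)),
        index=genus.counts.index, columns=genus.counts.columns,
    )
    refs = reference_genera(config)
    tbl = meta.table
    out = {}
    pats = tbl[tbl["role"] == "patient"]
    for pid, grp in pats.groupby("patient_id", sort=True):
        tps = set(grp["timepoint"])
        tp = "post28" if "post28" in tps else ("post10" if "post10" in tps else None)
        if tp is None:
            continue
        sid = grp[grp["timepoint"] == tp].index[0]
        out[pid] = float(
            logp.loc[sid, config.planted_genus] - logp.loc[sid, refs].mean()
        )
    return pd.Series(out, name="risk_score")


def generate_outcomes(
    meta: SampleMeta, counts: CountTable, config: SimConfig
) -> pd.Series:
    """Binary aGVHD labels: Bernoulli(sigmoid(alpha + beta * risk score +
    gamma * PTCy)) where the risk score is the early-post log ratio of the
    planted genus to the reference genera; alpha is calibrated so the
    marginal event rate matches ``config.event_rate``.

    Every patient gets a label (the clinical outcome exists regardless of
    sampling); for patients without any post-dose stool sample the microbiome
    term enters at its cohort mean.
    """
    rng = _rng(config, 2)
    x = _early_post_risk_score(meta, counts, config)
    tbl = meta.table
    ptcy = (
        tbl[tbl["role"] == "patient"]
        .groupby("patient_id")["prophylaxis"]
        .first()
        .eq("PTCy")
        .astype(float)
    )
    x = x.reindex(ptcy.index)
    z = ptcy
    xc = (x - x.mean()).fillna(0.0)
    zc = z - z.mean()
    lin = config.beta_outcome * xc + config.gamma_prophylaxis * zc

    def rate(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lin))))) - config.event_rate

    alpha = brentq(rate, -30, 30)
    probs = 1.0 / (1.0 + np.exp(-(alpha + lin)))
    labels = (rng.random(len(probs)) < probs).astype(int)
    out = pd.Series(labels, index=x.index, name="outcome")
    # write back into the metadata
    for pid, val in out.items():
        mask = tbl["patient_id"] == pid
        tbl.loc[mask & (tbl["role"] == "patient"), "outcome"] = val
    return out


def generate_metabolome(
    meta: SampleMeta, outcomes: pd.Series, config: SimConfig
) -> tuple[MetaboliteMatrix, pd.DataFrame, GroundTruth]:
    """Two-batch serum metabolite intensities with anchors and a planted
    protective metabolite.

    Returns ``(matrix, serum sample metadata, truth)``. Intensities are
    log-normal; a ``frac_collinear`` share of metabolites sits in blocks
    sharing a latent per-sample factor; non-detections are injected at
    ``zero_rate`` (a ``frac_poorly_detected`` share of metabolites uses
    ``poor_zero_rate`` instead, so the detection filter has work to do);
    target-batch values are multiplied by per-metabolite batch factors and
    ``n_anchor_samples`` reference samples are re-run in the target batch.
    The planted metabolite's log level is shifted down by
    ``protective_beta`` (log-SD units) in patients with the event.
    """
    rng = _rng(config, 3)
    tbl = meta.table
    pats = tbl[tbl["role"] == "patient"]
    pinfo = pats.groupby("patient_id").first()
    rows = []
    for pid, prow in pinfo.iterrows():
        for tp in ("baseline", "pre", "post28", "late"):
            if rng.random() >= config.serum_retention.get(tp, 1.0):
                continue
            rows.append(
                {
                    "sample_id": f"{pid}_serum_{tp}",
                    "patient_id": pid,
                    "timepoint": tp,
                    "arm": prow["arm"],
                    "prophylaxis": prow["prophylaxis"],
                    "outcome": outcomes.get(pid, pd.NA),
                }
            )
    serum_meta = pd.DataFrame(rows).set_index("sample_id")
    n_s = len(serum_meta)
    if config.n_anchor_samples > n_s:
        raise ValueError("n_anchor_samples exceeds available serum samples")
    m = config.n_metabolites
    met_ids = [f"M{i + 1:04d}" for i in range(m)]
    planted_id = met_ids[0]

    mu = rng.normal(8.0, 1.5, size=m)
    n_block_mets = int(config.frac_collinear * m)
    blocks = []
    # planted metabolite (index 0) stays out of collinear blocks
    candidates = list(range(1, m))
    bi = 0
    while bi + config.collinear_block_size <= n_block_mets:
        blocks.append(candidates[bi : bi + config.collinear_block_size])
        bi += config.collinear_block_size
    log_x = np.tile(mu, (n_s, 1)) + rng.normal(0.0, 1.0, size=(n_s, m))
    for block in blocks:
        f = rng.normal(0.0, 1.0, size=n_s)
        lam = rng.uniform(0.8, 1.2, size=len(block))
        noise = rng.normal(0.0, 0.4, size=(n_s, len(block)))
        log_x[:, block] = mu[block][None, :] + f[:, None] * lam[None, :] + noise
    # planted protective metabolite: lower in patients with the event
    event = pd.to_numeric(serum_meta["outcome"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    log_x[:, 0] = mu[0] + rng.normal(0.0, 1.0, size=n_s) - config.protective_beta * event

    intensities = np.exp(log_x)
    # batches and anchors
    is_target = rng.random(n_s) < 0.5
    batch = pd.Series(
        np.where(is_target, "target", "reference"), index=serum_meta.index
    )
    factors = np.exp(
        rng.uniform(
            np.log(config.batch_scale_range[0]),
            np.log(config.batch_scale_range[1]),
            size=m,
        )
    )
    vals = pd.DataFrame(intensities, index=serum_meta.index, columns=met_ids)
    vals.loc[is_target] = vals.loc[is_target].to_numpy() * factors[None, :]
    # anchors: reference samples re-run in the target batch
    ref_ids = list(vals.index[~is_target])
    anchor_refs = list(rng.choice(ref_ids, size=config.n_anchor_samples, replace=False))
    anchor_rows = vals.loc[anchor_refs].to_numpy() * factors[None, :]
    anchor_ids = [f"{sid}__rerun" for sid in anchor_refs]
    vals = pd.concat(
        [vals, pd.DataFrame(anchor_rows, index=anchor_ids, columns=met_ids)]
    )
    batch = pd.concat([batch, pd.Series("target", index=anchor_ids)])
    # zero inflation (the planted metabolite is always detected)
    poor = rng.random(m) < config.frac_poorly_detected
    zr = np.where(poor, config.poor_zero_rate, config.zero_rate)
    zr[0] = 0.0
    zero_mask = rng.random(vals.shape) < zr[None, :]
    arr = vals.to_numpy()
    arr[zero_mask] = 0.0
    vals = pd.DataFrame(arr, index=vals.index, columns=met_ids)
    mm = MetaboliteMatrix(
        intensities=vals,
        batch=batch,
        anchor_pairs=list(zip(anchor_refs, anchor_ids)),
    )
    truth = GroundTruth(
        planted_metabolite=planted_id,
        batch_factors=pd.Series(factors, index=met_ids),
        collinear_blocks=[[met_ids[i] for i in b] for b in blocks],
    )
    return mm, serum_meta, truth


def generate_topic_data(
    n_samples: int = 200,
    n_genera: int = 60,
    n_topics: int = 3,
    depth: int = 10_000,
    doc_alpha: float = 0.5,
    anchor_mass: float = 0.75,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Pure LDA-generative genus counts with disjoint anchor blocks.

    Each topic owns ``3`` anchor genera (shares 0.3/0.25/0.2 of
    ``anchor_mass``) and spreads the remaining mass uniformly over the shared
    background; per-sample topic weights are symmetric Dirichlet. Used for
    topic-model recovery checks where the generative process must match the
    model's own assumptions exactly.

    Returns ``(counts, true topic-genus matrix, true sample-topic weights)``.
    """
    rng = np.random.default_rng(seed)
    n_anchor = 3 * n_topics
    if n_genera <= n_anchor:
        raise ValueError("n_genera must exceed the anchor count")
    beta = np.zeros((n_topics, n_genera))
    for t in range(n_topics):
        beta[t, t * 3 : t * 3 + 3] = np.array([0.3, 0.25, 0.2]) / 0.75 * anchor_mass
        beta[t, n_anchor:] = (1 - anchor_mass) / (n_genera - n_anchor)
    theta = rng.dirichlet([doc_alpha] * n_topics, size=n_samples)
    W = np.vstack([rng.multinomial(depth, th @ beta) for th in theta])
    counts = pd.DataFrame(
        W,
        index=[f"s{i:03d}" for i in range(n_samples)],
        columns=[f"g{j:02d}" for j in range(n_genera)],
    )
    return counts, beta, theta


@dataclass
class SimulatedDataset:
    config: SimConfig
    meta: SampleMeta
    counts: CountTable
    outcomes: pd.Series
    metabolome: MetaboliteMatrix
    serum_meta: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimConfig) -> SimulatedDataset:
    """Run every generator in order and assemble the combined ground truth."""
    meta = generate_cohort(config)
    counts, truth = generate_microbiome(meta, config)
    outcomes = generate_outcomes(meta, counts, config)
    mm, serum_meta, met_truth = generate_metabolome(meta, outcomes, config)
    truth.outcome_labels = outcomes
    truth.planted_metabolite = met_truth.planted_metabolite
    truth.batch_factors = met_truth.batch_factors
    truth.collinear_blocks = met_truth.collinear_blocks
    return SimulatedDataset(config, meta, counts, outcomes, mm, serum_meta, truth)


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write the dataset as plain TSV/JSON artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.counts.counts.to_csv(out / "asv_counts.tsv", sep="\t")
    ds.counts.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
    ds.meta.table.to_csv(out / "sample_metadata.tsv", sep="\t")
    met = ds.metabolome.intensities.copy()
    met.insert(0, "batch", ds.metabolome.batch)
    met.to_csv(out / "metabolites.tsv", sep="\t")
    pd.DataFrame(ds.metabolome.anchor_pairs, columns=["reference", "target"]).to_csv(
        out / "anchor_pairs.tsv", sep="\t", index=False
    )
    ds.serum_meta.to_csv(out / "serum_metadata.tsv", sep="\t")
    truth = {
        "planted_genus": ds.truth.planted_genus,
        "planted_metabolite": ds.truth.planted_metabolite,
        "outcome_labels": {k: int(v) for k, v in ds.truth.outcome_labels.items()},
        "donor_asv_sets": {d: sorted(v) for d, v in ds.truth.donor_asv_sets.items()},
        "engrafted_counts": ds.truth.engrafted_counts,
        "batch_factors": {k: float(v) for k, v in ds.truth.batch_factors.items()},
        "collinear_blocks": ds.truth.collinear_blocks,
        "seed": ds.config.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    ds.truth.true_topic_term.to_csv(out / "true_topic_term.tsv", sep="\t")
    ds.truth.true_sample_topics.to_csv(out / "true_sample_topics.tsv", sep="\t")
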