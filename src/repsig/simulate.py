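"""Synthetic paired tumor/non-tumor repertoires with known ground truth.

The generator emulates the data structure the analysis consumes: per-patient
paired repertoire libraries across TCR chains (TRA/TRB/TRG/TRD) and the BCR
heavy chain (IGH with IgA/IgG/IgM isotypes), plus a censored-survival
clinical cohort and a numeric covariate table. Every random draw is keyed by
(seed, patient, tissue, chain), so runs are bit-reproducible and adding
patients never perturbs existing samples.

Generative model, in brief:

* Clone labels arise by V(D)J recombination: segments drawn from per-chain
  pools with fixed usage probabilities; CDR3 amino-acid sequences start with
  the canonical cysteine and continue uniformly over the 20-letter alphabet
  at a sampled length; nucleotides are a random synonymous codon spelling.
* Clone abundances follow a Zipf (power) law: the rank-i clone receives
  ``max(1, round(N_max / i**alpha))`` reads. Larger ``alpha`` means a more
  clonal (less even) repertoire, so evenness decreases monotonically in it.
* A ``shared_fraction`` portion of tumor clones copies labels from the
  paired non-tumor sample at matched abundance rank, so the Morisita-Horn
  index of the pair rises from exactly 0 (labels forced disjoint) to ~1.
* IGH clones acquire somatic hypermutation: each clone is mutated with
  probability ``shm_mutation_prob``; a mutated founder spawns a geometric-
  size star lineage whose members each differ from the founder at exactly
  one distinct CDR3aa position (pairwise distance 2), share V/J and isotype,
  and carry >= 1 V-region mismatch.
* Survival times are exponential with an injected hazard ratio between
  median-split groups of the prognostic feature (tumor IGH evenness),
  independently censored.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import Clonotype, RepertoireSample, write_airr_table
from .metrics import collapse, diversity
from . import io as rio

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: amino acid -> synonymous codons (standard genetic code, no stops)
_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

_TISSUES = ("non_tumor", "tumor")


def _default_segment_pools() -> dict[str, dict[str, list[str]]]:
    """Per-chain V/D/J label pools (gene-level names, no alleles)."""
    pools = {}
    sizes = {  # (n_V, n_D, n_J) roughly mirroring human locus sizes
        "TRA": (45, 0, 50),
        "TRB": (48, 2, 13),
        "TRG": (6, 0, 5),
        "TRD": (8, 3, 4),
        "IGH": (55, 25, 6),
    }
    for chain, (nv, nd, nj) in sizes.items():
        prefix = chain if chain != "IGH" else "IGH"
        pools[chain] = {
            "V": [f"{prefix}V{i + 1}" for i in range(nv)],
            "D": [f"{prefix}D{i + 1}" for i in range(nd)],
            "J": [f"{prefix}J{i + 1}" for i in range(nj)],
        }
    return pools


def _zipf_probs(n: int, skew: float = 1.5) -> np.ndarray:
    """Skewed usage probabilities for a segment pool."""
    w = 1.0 / np.arange(1, n + 1) ** (skew / 2.0)
    return w / w.sum()


@dataclass(slots=True)
class SimulationConfig:
    """Tunable world of the synthetic cohort.

    Defaults state the emulated study design: 64 patients with paired
    tumor/non-tumor libraries for all five chains; power-law clone
    abundances with tumor repertoires more clonal than non-tumor; weak
    tumor/non-tumor clonotype sharing; half of IgH clones somatically
    mutated; exponential survival with an injected hazard ratio of 0.4
    between high- and low-evenness groups.
    """

    n_patients: int = 64
    chains: tuple[str, ...] = ("TRA", "TRB", "TRG", "TRD", "IGH")
    clones_per_sample: int = 1000
    zipf_alpha_tumor: float = 1.2
    zipf_alpha_non_tumor: float = 1.0
    max_clone_count: int = 1000
    shared_fraction: float = 0.2
    cdr3_lengths: tuple[int, ...] = tuple(range(8, 21))
    cdr3_length_weights: tuple[float, ...] = (1, 2, 4, 7, 10, 12, 13, 12, 10, 7, 4, 2, 1)
    nonproductive_rate: float = 0.05
    #: 0 = identical V-usage in both tissues; 1 = fully reversed usage ranking
    #: in tumor (drives the tissue separation seen in usage ordination)
    tumor_v_usage_shift: float = 0.0
    # somatic hypermutation (IGH only)
    shm_mutation_prob: float = 0.5
    shm_lineage_p: float = 0.5  # geometric parameter for lineage size
    shm_mean_extra_mismatches: float = 3.0  # v_mismatches = 1 + Poisson(this)
    unknown_mismatch_rate: float = 0.0
    isotype_probs: dict[str, float] = field(
        default_factory=lambda: {"IgA": 0.3, "IgG": 0.3, "IgM": 0.4}
    )
    # clinical cohort
    male_prob: float = 55 / 64
    stage_advanced_prob: float = 33 / 64
    recurrence_probs: dict[str, float] = field(
        default_factory=lambda: {"yes": 35 / 64, "no": 24 / 64, "unknown": 5 / 64}
    )
    os_rate: float = 0.012  # events per month
    pfs_rate: float = 0.03
    rfs_rate: float = 0.025
    censor_rate: float = 0.015
    hazard_ratio: float = 0.4  # high prognostic feature -> lower hazard
    immune_score_coef: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.clones_per_sample <= 0 and self.shared_fraction > 0:
            raise ValueError("shared_fraction > 0 requires clones_per_sample > 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.zipf_alpha_tumor <= 0 or self.zipf_alpha_non_tumor <= 0:
            raise ValueError("zipf_alpha must be positive")
        for name in ("isotype_probs", "recurrence_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


@dataclass(slots=True)
class GroundTruth:
    """Generative values needed to recompute every expected test quantity."""

    samples: dict[str, dict] = field(default_factory=dict)
    patients: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"samples": self.samples, "patients": self.patients},
            indent=2,
            sort_keys=True,
            default=str,
        )


def _stream(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic per-(sample, purpose) random stream."""
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


def _zipf_counts(s: int, alpha: float, n_max: int) -> np.ndarray:
    ranks = np.arange(1, s + 1, dtype=float)
    return np.maximum(1, np.round(n_max / ranks**alpha)).astype(int)


def _draw_cdr3_aa(rng: np.random.Generator, lengths, weights) -> str:
    length = int(rng.choice(lengths, p=weights))
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "C" + body


def _aa_to_nt(rng: np.random.Generator, aa: str) -> str:
    return "".join(rng.choice(_CODONS[ch]) for ch in aa)


def _length_weights(config: SimulationConfig) -> np.ndarray:
    w = np.asarray(config.cdr3_length_weights, dtype=float)
    return w / w.sum()


def _draw_clone(
    rng: np.random.Generator,
    config: SimulationConfig,
    chain: str,
    pools: dict[str, dict[str, list[str]]],
    taken: set[str],
    v_probs: np.ndarray | None = None,
) -> tuple[str, str, str, str, str]:
    """One fresh (cdr3_aa, cdr3_nt, v, d, j) with a sample-unique CDR3aa."""
    lw = _length_weights(config)
    pool = pools[chain]
    if v_probs is None:
        v_probs = _zipf_probs(len(pool["V"]))
    v = str(rng.choice(pool["V"], p=v_probs))
    d = str(rng.choice(pool["D"], p=_zipf_probs(len(pool["D"])))) if pool["D"] else ""
    j = str(rng.choice(pool["J"], p=_zipf_probs(len(pool["J"]))))
    while True:
        aa = _draw_cdr3_aa(rng, config.cdr3_lengths, lw)
        if aa not in taken:
            taken.add(aa)
            return aa, _aa_to_nt(rng, aa), v, d, j


def _make_nonproductive(
    rng: np.random.Generator,
    config: SimulationConfig,
    chain: str,
    pools,
    taken: set[str],
    kind: int,
) -> tuple[str, str, str, str, str]:
    """A clone violating exactly one productive rule (cycled by ``kind``)."""
    aa, nt, v, d, j = _draw_clone(rng, config, chain, pools, taken)
    kind = kind % 3
    if kind == 0:  # stop codon
        pos = int(rng.integers(1, len(aa)))
        aa = aa[:pos] + "*" + aa[pos + 1 :]
        nt = nt[: 3 * pos] + "TAA" + nt[3 * pos + 3 :]
    elif kind == 1:  # out of frame
        nt = nt[:-1]
    else:  # too short
        aa = aa[:3]
        nt = nt[:9]
    return aa, nt, v, d, j


def simulate_pair(
    config: SimulationConfig,
    patient_id: str,
    chain: str = "TRB",
) -> tuple[RepertoireSample, RepertoireSample, GroundTruth]:
    """Paired tumor/non-tumor repertoires for one patient and chain.

    The non-tumor repertoire is drawn first; ``round(shared_fraction * S)``
    tumor clones then copy non-tumor labels at matched abundance rank, the
    rest are fresh labels rejection-sampled to be disjoint from the paired
    sample. Nonproductive clones (stop codon, off-frame, too-short CDR3) are
    appended at ``nonproductive_rate`` to exercise the QC filter; the ground
    truth records their ids.
    """
    config.validate()
    if chain not in config.chains:
        raise ValueError(f"chain {chain!r} not enabled in config")
    pools = _default_segment_pools()
    s = config.clones_per_sample
    truth = GroundTruth()

    samples: dict[str, RepertoireSample] = {}
    non_tumor_clones: list[tuple[str, str, str, str, str]] = []
    non_tumor_aa: set[str] = set()

    for tissue in _TISSUES:
        rng = _stream(config.seed, patient_id, tissue, chain)
        alpha = (
            config.zipf_alpha_tumor if tissue == "tumor" else config.zipf_alpha_non_tumor
        )
        counts = _zipf_counts(s, alpha, config.max_clone_count)
        taken: set[str] = set(non_tumor_aa) if tissue == "tumor" else set()
        records: list[tuple[str, str, str, str, str]] = []
        base_v = _zipf_probs(len(pools[chain]["V"]))
        if tissue == "tumor" and config.tumor_v_usage_shift > 0:
            w = config.tumor_v_usage_shift
            v_probs = (1 - w) * base_v + w * base_v[::-1]
        else:
            v_probs = base_v

        if tissue == "non_tumor":
            for _ in range(s):
                records.append(_draw_clone(rng, config, chain, pools, taken, v_probs))
            non_tumor_clones = records
            non_tumor_aa = {r[0] for r in records}
        else:
            n_shared = int(round(config.shared_fraction * s))
            shared_ranks = set(
                rng.choice(s, size=n_shared, replace=False).tolist()
            ) if n_shared else set()
            for rank in range(s):
                if rank in shared_ranks:
                    records.append(non_tumor_clones[rank])
                else:
                    records.append(_draw_clone(rng, config, chain, pools, taken, v_probs))

        clonotypes = []
        for i, ((aa, nt, v, d, j), count) in enumerate(zip(records, counts)):
            clonotypes.append(
                Clonotype(
                    clone_id=f"{patient_id}_{tissue}_{chain}_{i:05d}",
                    count=int(count),
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    v_call=v,
                    d_call=d,
                    j_call=j,
                    chain=chain,
                    v_mismatches=None,
                )
            )
        n_bad = int(round(config.nonproductive_rate * s))
        bad_ids = []
        for k in range(n_bad):
            aa, nt, v, d, j = _make_nonproductive(rng, config, chain, pools, taken, k)
            cid = f"{patient_id}_{tissue}_{chain}_bad{k:04d}"
            bad_ids.append(cid)
            clonotypes.append(
                Clonotype(
                    clone_id=cid,
                    count=int(rng.integers(1, 6)),
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    v_call=v,
                    d_call=d,
                    j_call=j,
                    chain=chain,
                )
            )
        sample = RepertoireSample(
            patient_id=patient_id, tissue=tissue, chain=chain, clonotypes=clonotypes
        )
        samples[tissue] = sample
        truth.samples[sample.sample_id] = {
            "zipf_alpha": alpha,
            "shared_fraction": config.shared_fraction if tissue == "tumor" else None,
            "n_productive": s,
            "n_nonproductive": n_bad,
            "nonproductive_ids": bad_ids,
            "total_count": int(sum(c.count for c in clonotypes)),
        }

    return samples["tumor"], samples["non_tumor"], truth


def simulate_shm(
    config: SimulationConfig,
    sample: RepertoireSample,
) -> RepertoireSample:
    """Attach SHM structure (mutation status, star lineages, isotypes) to IGH.

    Each productive clone becomes a mutated founder with probability
    ``shm_mutation_prob``; founders spawn ``Geometric(shm_lineage_p) - 1``
    descendants, each differing from the founder at exactly one distinct
    CDR3aa position (so descendant pairs are at Hamming distance 2 and the
    lineage network is a star). Members share V/J and isotype and carry
    ``v_mismatches >= 1``; unmutated clones carry 0 (or missing at
    ``unknown_mismatch_rate``).
    """
    if sample.chain != "IGH":
        raise ValueError(f"SHM simulation applies to IGH samples, got {sample.chain!r}")
    rng = _stream(config.seed, sample.patient_id, sample.tissue, "IGH", "shm")
    isotypes = sorted(config.isotype_probs)
    iso_p = np.array([config.isotype_probs[k] for k in isotypes])
    out: list[Clonotype] = []
    from dataclasses import replace

    for c in sample.clonotypes:
        iso = str(rng.choice(isotypes, p=iso_p))
        productive = rio.is_productive(c)
        mutated = productive and bool(rng.random() < config.shm_mutation_prob)
        if not mutated:
            vmm: int | None = 0
            if config.unknown_mismatch_rate and rng.random() < config.unknown_mismatch_rate:
                vmm = None
            out.append(replace(c, isotype=iso, v_mismatches=vmm))
            continue
        founder_vmm = 1 + int(rng.poisson(config.shm_mean_extra_mismatches))
        founder = replace(c, isotype=iso, v_mismatches=founder_vmm)
        out.append(founder)
        lineage_size = int(rng.geometric(config.shm_lineage_p))
        n_desc = min(lineage_size - 1, len(c.cdr3_aa) - 1)
        if n_desc <= 0:
            continue
        positions = rng.choice(
            np.arange(1, len(c.cdr3_aa)), size=n_desc, replace=False
        )
        for k, pos in enumerate(sorted(int(p) for p in positions)):
            old = c.cdr3_aa[pos]
            new = str(rng.choice([a for a in AMINO_ACIDS if a != old]))
            aa = c.cdr3_aa[:pos] + new + c.cdr3_aa[pos + 1 :]
            nt = c.cdr3_nt[: 3 * pos] + _aa_to_nt(rng, new) + c.cdr3_nt[3 * pos + 3 :]
            out.append(
                Clonotype(
                    clone_id=f"{c.clone_id}_m{k}",
                    count=int(rng.integers(1, 6)),
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    v_call=c.v_call,
                    d_call=c.d_call,
                    j_call=c.j_call,
                    chain="IGH",
                    isotype=iso,
                    v_mismatches=1 + int(rng.poisson(config.shm_mean_extra_mismatches)),
                )
            )
    return RepertoireSample(
        patient_id=sample.patient_id,
        tissue=sample.tissue,
        chain="IGH",
        clonotypes=out,
    )


def simulate_survival_cohort(
    n: int,
    rate: float,
    hazard_ratio: float,
    censor_rate: float,
    rng: np.random.Generator,
    feature: np.ndarray | None = None,
) -> pd.DataFrame:
    """Light-weight survival cohort with an injected median-split effect.

    Draws a latent prognostic feature (standard normal unless given), sets
    each patient's hazard to ``rate * hazard_ratio**high`` where ``high``
    marks values above the cohort median (so a hazard ratio < 1 means high
    feature values protect), and returns exponential event times under
    independent exponential censoring.
    """
    if feature is None:
        feature = rng.normal(size=n)
    feature = np.asarray(feature, dtype=float)
    high = feature > np.median(feature)
    hazard = rate * np.power(hazard_ratio, high.astype(float))
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / censor_rate, size=n)
    months = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {"feature": feature, "months": months, "event": event, "high": high}
    )


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
) -> tuple[dict[str, list[Path]], GroundTruth]:
    """Write a full synthetic cohort to disk and return its ground truth.

    Emits one AIRR Rearrangement TSV per (patient, tissue, chain), a
    clinical CSV (sex, age band, TNM stage, recurrence, PFS/RFS/OS times and
    events), a covariate TSV whose immune score is correlated with tumor IGH
    richness at the configured coefficient, and a JSON ground-truth
    manifest. Byte-identical for identical (config, seed).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()
    repertoire_paths: list[Path] = []
    patient_ids = [f"P{i + 1:03d}" for i in range(config.n_patients)]

    prognostic: dict[str, float] = {}
    richness_t: dict[str, float] = {}
    for pid in patient_ids:
        for chain in config.chains:
            tumor, non_tumor, pair_truth = simulate_pair(config, pid, chain)
            if chain == "IGH":
                tumor = simulate_shm(config, tumor)
                non_tumor = simulate_shm(config, non_tumor)
            truth.samples.update(pair_truth.samples)
            for sample in (non_tumor, tumor):
                path = out_dir / f"{pid}_{sample.tissue}_{chain}.tsv"
                write_airr_table(sample.clonotypes, path)
                repertoire_paths.append(path)
            if chain == "IGH":
                filtered = rio.filter_productive(tumor.clonotypes)
                prof = collapse(
                    RepertoireSample(pid, "tumor", "IGH", filtered), "CDR3aa"
                )
                d = diversity(prof)
                prognostic[pid] = d.nsde
                richness_t[pid] = float(d.richness)
    if not prognostic:  # no IGH chain enabled: fall back to first chain evenness
        for pid in patient_ids:
            rng = _stream(config.seed, pid, "fallback")
            prognostic[pid] = float(rng.random())
            richness_t[pid] = float(rng.random())

    # clinical cohort with survival tied to the prognostic feature
    feature = np.array([prognostic[p] for p in patient_ids])
    high = feature > np.median(feature)
    clin_rows = []
    for i, pid in enumerate(patient_ids):
        rng = _stream(config.seed, pid, "clinical")
        sex = "male" if rng.random() < config.male_prob else "female"
        age_band = str(rng.choice(["<40", "40-60", ">60"], p=[0.2, 0.6, 0.2]))
        stage = 2 + int(rng.integers(0, 2)) if rng.random() < config.stage_advanced_prob else 1
        rec_states = sorted(config.recurrence_probs)
        rec_p = np.array([config.recurrence_probs[k] for k in rec_states])
        recurrence = str(rng.choice(rec_states, p=rec_p))
        row: dict[str, object] = {
            "patient_id": pid,
            "sex": sex,
            "age_band": age_band,
            "tnm_stage": stage,
            "recurrence": recurrence,
        }
        for endpoint, rate in (
            ("os", config.os_rate),
            ("pfs", config.pfs_rate),
            ("rfs", config.rfs_rate),
        ):
            hazard = rate * (config.hazard_ratio if high[i] else 1.0)
            t_event = rng.exponential(1.0 / hazard)
            t_censor = rng.exponential(1.0 / config.censor_rate)
            row[f"{endpoint}_months"] = round(min(t_event, t_censor), 3)
            row[f"{endpoint}_event"] = int(t_event <= t_censor)
        clin_rows.append(row)
        truth.patients[pid] = {
            "prognostic_feature": float(feature[i]),
            "high_feature": bool(high[i]),
            "stage": stage,
            "recurrence": recurrence,
            "hazard_ratio_applied": config.hazard_ratio if high[i] else 1.0,
        }
    clinical_path = out_dir / "clinical.csv"
    pd.DataFrame(clin_rows).to_csv(clinical_path, index=False, lineterminator="\n")

    # covariate: immune score correlated with tumor IGH richness
    rich = np.array([richness_t[p] for p in patient_ids])
    z = (rich - rich.mean()) / rich.std() if rich.std() > 0 else np.zeros_like(rich)
    rng_cov = _stream(config.seed, "covariates")
    noise = rng_cov.normal(size=len(patient_ids))
    rho = config.immune_score_coef
    immune = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
    covariate_path = out_dir / "covariates.tsv"
    pd.DataFrame({"patient_id": patient_ids, "immune_score": np.round(immune, 6)}).to_csv(
        covariate_path, sep="\t", index=False, lineterminator="\n"
    )

    manifest_path = out_dir / "manifest.json"
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_repertoire_files": len(repertoire_paths),
        "files": sorted(p.name for p in repertoire_paths),
        "ground_truth": {"samples": truth.samples, "patients": truth.patients},
    }
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    paths = {
        "repertoires": repertoire_paths,
        "clinical": [clinical_path],
        "covariates": [covariate_path],
        "manifest": [manifest_path],
    }
    return paths, truth
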