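"""Deterministic generators for synthetic paired genomics/metabolomics data.

Two generators cover the two halves of the scoring problem:

* :func:`simulate_occurrence` plants true GCF-MF links as near-identical
  strain sets (the MF set is a noisy copy of its GCF's) amid independent
  decoy families, exercising the correlation score end to end;
* :func:`simulate_spectra` draws binary fingerprints and produces spectra
  through a fixed random linear map from fingerprint bits to peak-channel
  intensities (plus Gaussian noise), giving the kernel regression a learnable
  spectrum->fingerprint relationship whose recovery is checkable at desk
  scale.  This is deliberately a linear-Gaussian model, not an in-silico
  fragmentation model.

:func:`simulate_linked_dataset` wires the two together: each planted
occurrence link gets a structure for its gene cluster family and a matching
spectrum for its molecular family, so correlation and feature scores can be
computed for the same links.  All generators are pure functions of their
parameters (seed included), using numpy's PCG64 generator for cross-platform
reproducibility.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from metabolink.core_model import (
    BGC,
    GCF,
    MolecularFamily,
    OccurrenceData,
    Spectrum,
    Strain,
)
from metabolink.iokr import FingerprintVector
from metabolink.io_formats import DatasetBundle

__all__ = [
    "OccurrenceSimParams",
    "SpectrumSimParams",
    "LinkedDataset",
    "simulate_occurrence",
    "simulate_spectra",
    "simulate_linked_dataset",
    "fig2_fixture",
]


@dataclass(frozen=True)
class OccurrenceSimParams:
    """Conditions for the strain-occurrence simulation.

    Defaults describe a modest strain collection (60 strains) with 10
    planted links whose MF strain sets deviate from their GCF's in 5% of
    strains (detection noise), plus 50 decoy families on each side drawn
    independently with the same 50% per-strain presence probability.
    """

    n_strains: int = 60
    n_true_links: int = 10
    n_decoy_gcfs: int = 50
    n_decoy_mfs: int = 50
    base_presence_prob: float = 0.5
    flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("need at least one strain")
        if min(self.n_true_links, self.n_decoy_gcfs, self.n_decoy_mfs) < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.base_presence_prob, self.flip_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SpectrumSimParams:
    """Conditions for the paired spectrum/fingerprint simulation.

    Fingerprints are drawn with exactly ``n_fingerprint_bits // 2`` bits set
    so that inner-product ranking is not biased toward dense fingerprints,
    and are unique across the training set and the candidate set.  Each
    spectrum has one peak per channel at a fixed channel m/z; intensities
    are ``W @ bits`` for a fixed uniform random map W, plus optional noise.
    """

    n_fingerprint_bits: int = 16
    n_peak_channels: int = 30
    n_train: int = 200
    n_test: int = 40
    n_candidates: int = 40
    peak_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_fingerprint_bits, self.n_peak_channels, self.n_train) < 1:
            raise ValueError("counts must be positive")
        if self.n_test < 1 or self.n_candidates < self.n_test:
            raise ValueError("need n_candidates >= n_test >= 1")
        if self.peak_noise_sd < 0:
            raise ValueError("peak_noise_sd must be >= 0")


def _strain_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _draw_nonempty_subset(rng: np.random.Generator, ids: Sequence[str], p: float) -> frozenset[str]:
    # redraw until non-empty so every family has at least one strain
    while True:
        mask = rng.random(len(ids)) < p
        if mask.any():
            return frozenset(np.asarray(ids)[mask].tolist())


def simulate_occurrence(
    params: OccurrenceSimParams,
) -> tuple[OccurrenceData, list[tuple[str, str]]]:
    """Simulate strain-occurrence data with planted GCF-MF links.

    For each planted link the GCF strain set is drawn per strain with
    ``base_presence_prob``; the MF strain set starts as a copy and each
    strain's membership is flipped independently with ``flip_prob``.  Decoy
    families on both sides are drawn independently.  Returns the occurrence
    data and the planted (gcf_id, mf_id) truth list; fully reproducible
    from the seed.
    """
    rng = np.random.default_rng(params.seed)
    ids = _strain_ids(params.n_strains)
    arr = np.asarray(ids)
    gcf_occ: dict[str, frozenset[str]] = {}
    mf_occ: dict[str, frozenset[str]] = {}
    truth = []
    for i in range(params.n_true_links):
        gmask = rng.random(len(ids)) < params.base_presence_prob
        while not gmask.any():
            gmask = rng.random(len(ids)) < params.base_presence_prob
        mmask = gmask ^ (rng.random(len(ids)) < params.flip_prob)
        while not mmask.any():
            mmask = gmask ^ (rng.random(len(ids)) < params.flip_prob)
        gid, mid = f"GCF_T{i + 1:03d}", f"MF_T{i + 1:03d}"
        gcf_occ[gid] = frozenset(arr[gmask].tolist())
        mf_occ[mid] = frozenset(arr[mmask].tolist())
        truth.append((gid, mid))
    for i in range(params.n_decoy_gcfs):
        gcf_occ[f"GCF_D{i + 1:03d}"] = _draw_nonempty_subset(
            rng, ids, params.base_presence_prob
        )
    for i in range(params.n_decoy_mfs):
        mf_occ[f"MF_D{i + 1:03d}"] = _draw_nonempty_subset(
            rng, ids, params.base_presence_prob
        )
    occ = OccurrenceData(
        strains=tuple(ids), gcf_occurrence=gcf_occ, mf_occurrence=mf_occ
    )
    return occ, truth


def _unique_fingerprints(
    rng: np.random.Generator, count: int, n_bits: int
) -> np.ndarray:
    """Draw ``count`` distinct binary vectors with exactly n_bits//2 bits set."""
    k = max(1, n_bits // 2)
    seen: set[bytes] = set()
    rows = []
    while len(rows) < count:
        bits = np.zeros(n_bits, dtype=np.int64)
        bits[rng.choice(n_bits, size=k, replace=False)] = 1
        key = bits.tobytes()
        if key not in seen:
            seen.add(key)
            rows.append(bits)
    return np.stack(rows)


_CHANNEL_MZ_START = 100.0
_CHANNEL_MZ_STEP = 10.0


def _spectrum_from_fp(
    sid: str,
    bits: np.ndarray,
    W: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
) -> Spectrum:
    intensity = W @ bits
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 1e-9, None)
    mz = _CHANNEL_MZ_START + _CHANNEL_MZ_STEP * np.arange(len(intensity))
    return Spectrum(id=sid, peaks=tuple(zip(mz.tolist(), intensity.tolist())))


def simulate_spectra(
    params: SpectrumSimParams,
) -> tuple[
    list[tuple[Spectrum, FingerprintVector]],
    list[tuple[Spectrum, str]],
    list[tuple[str, FingerprintVector]],
]:
    """Simulate paired spectra/fingerprints from a known generative map.

    Returns ``(training_pairs, test_pairs, candidates)``: training pairs of
    (spectrum, fingerprint); test pairs of (spectrum, true structure key);
    and the candidate list of (key, fingerprint).  The first ``n_test``
    candidates are the test truths, the rest decoys.  Reproducible from the
    seed.
    """
    rng = np.random.default_rng(params.seed)
    n_bits = params.n_fingerprint_bits
    all_fps = _unique_fingerprints(
        rng, params.n_train + params.n_candidates, n_bits
    )
    W = rng.uniform(0.0, 1.0, size=(params.n_peak_channels, n_bits))

    train_fps = all_fps[: params.n_train]
    cand_fps = all_fps[params.n_train :]
    training = [
        (
            _spectrum_from_fp(f"train_{i + 1:04d}", bits, W, rng, params.peak_noise_sd),
            FingerprintVector(bits=tuple(bits.tolist())),
        )
        for i, bits in enumerate(train_fps)
    ]
    candidates = [
        (f"STRUCT_{i + 1:04d}", FingerprintVector(bits=tuple(bits.tolist())))
        for i, bits in enumerate(cand_fps)
    ]
    test = [
        (
            _spectrum_from_fp(
                f"test_{i + 1:04d}", cand_fps[i], W, rng, params.peak_noise_sd
            ),
            candidates[i][0],
        )
        for i in range(params.n_test)
    ]
    return training, test, candidates


@dataclass
class LinkedDataset:
    """A fully wired synthetic dataset: occurrence data plus IOKR inputs.

    ``gcf_structures`` maps each GCF id to the (bgc_id, structure_key,
    fingerprint) triples of its structure-annotated members;
    ``mf_spectra`` maps each MF id to its member spectra.
    """

    bundle: DatasetBundle
    occurrence: OccurrenceData
    truth: list[tuple[str, str]]
    training_pairs: list[tuple[Spectrum, FingerprintVector]]
    gcf_structures: dict[str, list[tuple[str, str, FingerprintVector]]]
    mf_spectra: dict[str, list[Spectrum]] = field(default_factory=dict)


def simulate_linked_dataset(
    occ_params: OccurrenceSimParams,
    spec_params: SpectrumSimParams | None = None,
) -> LinkedDataset:
    """Simulate a dataset where planted links agree on both evidence axes.

    Occurrence data come from :func:`simulate_occurrence`.  Every GCF gets
    one structure-annotated BGC and every MF one spectrum; a planted link's
    GCF structure and MF spectrum share the same underlying fingerprint
    (drawn as in :func:`simulate_spectra`), while decoy families get
    independent fingerprints, so planted links also score high on the
    feature axis.  A separate training set from the same generative map is
    returned for fitting the kernel regression.
    """
    spec_params = spec_params or SpectrumSimParams(seed=occ_params.seed + 1)
    occ, truth = simulate_occurrence(occ_params)

    rng = np.random.default_rng(spec_params.seed)
    n_bits = spec_params.n_fingerprint_bits
    gcf_ids = sorted(occ.gcf_occurrence)
    mf_ids = sorted(occ.mf_occurrence)
    true_gcf_to_mf = dict(truth)

    # one fingerprint per GCF and per unlinked MF, plus the training pool
    n_structures = len(gcf_ids) + len(mf_ids) - len(truth)
    all_fps = _unique_fingerprints(
        rng, spec_params.n_train + n_structures, n_bits
    )
    W = rng.uniform(0.0, 1.0, size=(spec_params.n_peak_channels, n_bits))

    training = [
        (
            _spectrum_from_fp(
                f"train_{i + 1:04d}", all_fps[i], W, rng, spec_params.peak_noise_sd
            ),
            FingerprintVector(bits=tuple(all_fps[i].tolist())),
        )
        for i in range(spec_params.n_train)
    ]

    pool = iter(range(spec_params.n_train, len(all_fps)))
    gcf_fp: dict[str, np.ndarray] = {gid: all_fps[next(pool)] for gid in gcf_ids}
    mf_fp: dict[str, np.ndarray] = {}
    for gid, mid in truth:
        mf_fp[mid] = gcf_fp[gid]  # shared fingerprint: the planted signal
    for mid in mf_ids:
        if mid not in mf_fp:
            mf_fp[mid] = all_fps[next(pool)]

    strains = [Strain(id=s) for s in occ.strains]
    bgcs, gcfs, fingerprints = [], [], {}
    gcf_structures: dict[str, list[tuple[str, str, FingerprintVector]]] = {}
    for gid in gcf_ids:
        key = f"STRUCT_{gid}"
        fp = FingerprintVector(bits=tuple(gcf_fp[gid].tolist()))
        fingerprints[key] = fp
        members = []
        for j, strain in enumerate(sorted(occ.gcf_occurrence[gid])):
            bid = f"BGC_{gid}_{j + 1}"
            bgcs.append(
                BGC(
                    id=bid,
                    strain=strain,
                    candidate_structures=(key,) if j == 0 else (),
                )
            )
            members.append(bid)
        gcfs.append(GCF(id=gid, members=frozenset(members)))
        gcf_structures[gid] = [(members[0], key, fp)]

    spectra, mfs = [], []
    mf_spectra: dict[str, list[Spectrum]] = {}
    for mid in mf_ids:
        spec = _spectrum_from_fp(
            f"spec_{mid}", mf_fp[mid], W, rng, spec_params.peak_noise_sd
        )
        spec = Spectrum(
            id=spec.id,
            peaks=spec.peaks,
            strain_set=frozenset(occ.mf_occurrence[mid]),
        )
        spectra.append(spec)
        mfs.append(MolecularFamily(id=mid, members=frozenset({spec.id})))
        mf_spectra[mid] = [spec]

    bundle = DatasetBundle(
        strains=strains,
        bgcs=bgcs,
        gcfs=gcfs,
        spectra=spectra,
        mfs=mfs,
        fingerprints=fingerprints,
        validated_links=list(truth),
    )
    return LinkedDataset(
        bundle=bundle,
        occurrence=occ,
        truth=truth,
        training_pairs=training,
        gcf_structures=gcf_structures,
        mf_spectra=mf_spectra,
    )


def fig2_fixture() -> DatasetBundle:
    """Two-link worked example on an 8-strain population.

    The *top* pair is a gene cluster family containing a BGC from every one
    of the 8 strains, linked to a molecular family present in 3 of them
    (m=3, g=8, o=3).  The *bottom* pair is a GCF and an MF consisting of the
    same 2 strains (m=g=o=2).  The raw correlation scores are 30 and 26 —
    the all-strain family wins — while the standardised scores are 0.0 and
    about 2.65, correctly favouring the bottom pair's perfect correspondence.
    """
    ids = _strain_ids(8)
    strains = [Strain(id=s) for s in ids]
    bgcs = [BGC(id=f"BGC_top_{i + 1}", strain=s) for i, s in enumerate(ids)]
    bgcs += [BGC(id=f"BGC_bot_{i + 1}", strain=s) for i, s in enumerate(ids[:2])]
    gcfs = [
        GCF(id="GCF_top", members=frozenset(b.id for b in bgcs[:8])),
        GCF(id="GCF_bot", members=frozenset(b.id for b in bgcs[8:])),
    ]
    # one peak-list per MF; peak content is irrelevant to correlation scoring
    spec_top = Spectrum(
        id="spec_top",
        peaks=((100.0, 1.0), (200.0, 0.5)),
        precursor_mz=300.0,
        strain_set=frozenset(ids[:3]),
    )
    spec_bot = Spectrum(
        id="spec_bot",
        peaks=((150.0, 1.0), (250.0, 0.25)),
        precursor_mz=350.0,
        strain_set=frozenset(ids[:2]),
    )
    mfs = [
        MolecularFamily(id="MF_top", members=frozenset({"spec_top"})),
        MolecularFamily(id="MF_bot", members=frozenset({"spec_bot"})),
    ]
    return DatasetBundle(
        strains=strains,
        bgcs=bgcs,
        gcfs=gcfs,
        spectra=[spec_top, spec_bot],
        mfs=mfs,
        validated_links=[("GCF_bot", "MF_bot")],
    )
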