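"""Feature-based link scoring with Input-Output Kernel Regression (IOKR).

IOKR learns a map ``h`` from MS2 spectra into molecular-fingerprint space by
kernel ridge regression: given training pairs (x_i, y_i) of spectra and
fingerprints, the prediction for a query spectrum x is

    h(x) = sum_j K_x(x, x_j) c_j,      (K_X + lambda I) C = Y,

where K_x is a kernel on spectra and the rows of C are the dual coefficient
vectors c_j.  A candidate structure y with fingerprint phi(y) is scored by the
inner product <h(x), phi(y)>, and a candidate set is ranked by that score.

The spectrum kernel is the Probability Product Kernel (PPK): each spectrum is
treated as a uniform mixture of axis-aligned 2-D Gaussians centred at its
(m/z, intensity) peaks, and the kernel is the integral of the product of two
such mixture densities.  Before the kernel is evaluated, query spectra are
filtered to the peaks present in the training data (a denoising step) and
intensities are rescaled to unit maximum per spectrum.

A link between a gene cluster family and a molecular family is scored by the
best-scoring (spectrum, candidate structure) pair across the family members;
links whose gene cluster family has no structure-annotated member are
*undefined* (reported as missing, never as 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from metabolink.core_model import BGC, Spectrum

__all__ = [
    "SpectrumKernelParams",
    "FingerprintVector",
    "IOKRModel",
    "LinkScore",
    "RankedCandidate",
    "FingerprintBackend",
    "PrecomputedFingerprinter",
    "RDKitFingerprinter",
    "structure_key",
    "fingerprint",
    "filter_peaks",
    "ppk",
    "fit_iokr",
    "score_pair",
    "predict_fingerprint",
    "rank_candidates",
    "aggregate_gcf_mf",
    "topn_curve",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SpectrumKernelParams:
    """PPK hyperparameters.

    sigma_mz : Gaussian width on the m/z axis (Da).  Default 0.5 Da, on the
        order of unit-resolution instrument accuracy for fragment peaks.
    sigma_int : Gaussian width on the intensity axis, in units of the
        per-spectrum maximum (intensities are rescaled to unit maximum by
        default, so 0.5 means "half the base peak").
    normalise : cosine-normalise the kernel so K(x, x) = 1.
    peak_match_tol : tolerance (Da) for the training-peak filter applied to
        query spectra.
    rescale_intensity : divide each spectrum's intensities by their maximum
        before the kernel; switch off for pre-normalised data.
    """

    sigma_mz: float = 0.5
    sigma_int: float = 0.5
    normalise: bool = True
    peak_match_tol: float = 0.1
    rescale_intensity: bool = True

    def __post_init__(self) -> None:
        if self.sigma_mz <= 0 or self.sigma_int <= 0:
            raise ValueError("kernel widths must be positive")
        if self.peak_match_tol < 0:
            raise ValueError("peak_match_tol must be >= 0")


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length binary molecular fingerprint.

    ``block_labels`` names the concatenated fingerprint families (purely
    descriptive; the scoring treats the vector as one bit string).
    """

    bits: tuple[int, ...]
    block_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=float)


@dataclass(frozen=True)
class LinkScore:
    """Aggregated IOKR score for a GCF-MF link and the pair attaining it."""

    value: float
    argmax_pair: tuple[str, str]  # (spectrum id, BGC id)


@dataclass(frozen=True)
class RankedCandidate:
    key: str
    score: float
    rank: int  # 1-based position in the descending ordering


# ---------------------------------------------------------------------------
# fingerprint backends


class FingerprintBackend(Protocol):
    def __call__(self, structure: str) -> FingerprintVector: ...


class PrecomputedFingerprinter:
    """Look fingerprints up from a structure-key -> bit-string table."""

    def __init__(self, table: Mapping[str, FingerprintVector]):
        self.table = dict(table)

    @classmethod
    def from_tsv(cls, path) -> "PrecomputedFingerprinter":
        from metabolink.io_formats import read_fingerprints

        return cls(read_fingerprints(path))

    def __call__(self, structure: str) -> FingerprintVector:
        key = structure_key(structure)
        try:
            return self.table[key]
        except KeyError:
            raise KeyError(
                f"no precomputed fingerprint for structure {structure!r} "
                f"(key {key!r})"
            ) from None


class RDKitFingerprinter:
    """Concatenate three fingerprint families computed with RDKit.

    The families are MACCS keys, the RDKit path-based (pattern) fingerprint
    and a hashed Morgan (circular, radius 2) fingerprint.  Together they mix
    curated substructure keys with topological features, which is the design
    intent behind concatenating multiple fingerprint families; exact parity
    with any other toolkit's bit definitions is not attempted.
    """

    block_labels = ("maccs", "rdkit_path", "morgan_r2")

    def __init__(self, n_bits_path: int = 1024, n_bits_morgan: int = 1024):
        try:
            from rdkit import Chem  # noqa: F401
        except ImportError as exc:  # pragma: no cover - rdkit is an extra
            raise ImportError(
                "RDKitFingerprinter requires the 'rdkit' package "
                "(install the [chem] extra)"
            ) from exc
        self.n_bits_path = n_bits_path
        self.n_bits_morgan = n_bits_morgan

    def __call__(self, structure: str) -> FingerprintVector:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {structure!r}")
        maccs = list(MACCSkeys.GenMACCSKeys(mol))
        rdk = list(
            rdFingerprintGenerator.GetRDKitFPGenerator(
                fpSize=self.n_bits_path
            ).GetFingerprint(mol)
        )
        morgan = list(
            rdFingerprintGenerator.GetMorganGenerator(
                radius=2, fpSize=self.n_bits_morgan
            ).GetFingerprint(mol)
        )
        return FingerprintVector(
            bits=tuple(maccs + rdk + morgan), block_labels=self.block_labels
        )


def structure_key(structure: str) -> str:
    """Canonical identity key for a structure reference.

    InChIKeys are truncated to their first (skeleton) block, so stereoisomers
    differing only in chirality share one key; other references (SMILES,
    arbitrary ids) are used verbatim.
    """
    parts = structure.split("-")
    if (
        len(parts) == 3
        and len(parts[0]) == 14
        and len(parts[1]) == 10
        and parts[0].isalpha()
        and parts[0].isupper()
    ):
        return parts[0]
    return structure


def fingerprint(structure: str, backend: FingerprintBackend) -> FingerprintVector:
    """Map a structure reference to its binary fingerprint via a backend."""
    return backend(structure)


# ---------------------------------------------------------------------------
# spectrum kernel


def filter_peaks(
    spectrum: Spectrum, reference_peaks: Sequence[float], tol: float
) -> Spectrum:
    """Keep only peaks within ``tol`` Da of some reference m/z.

    The reference list is the pool of training-spectrum peaks; filtering query
    spectra against it denoises them before the kernel is applied.
    """
    refs = np.asarray(reference_peaks, dtype=float)
    if refs.size == 0:
        kept: tuple[tuple[float, float], ...] = ()
    elif np.isinf(tol):
        kept = spectrum.peaks
    else:
        mz = np.array([p[0] for p in spectrum.peaks])
        idx = np.clip(np.searchsorted(refs, mz), 1, refs.size) - 1
        lo = np.abs(mz - refs[idx])
        hi = np.abs(mz - refs[np.minimum(idx + 1, refs.size - 1)])
        keep = np.minimum(lo, hi) <= tol
        kept = tuple(p for p, k in zip(spectrum.peaks, keep) if k)
    return Spectrum(
        id=spectrum.id,
        peaks=kept,
        precursor_mz=spectrum.precursor_mz,
        strain_set=spectrum.strain_set,
    )


def _peak_arrays(
    spectrum: Spectrum, params: SpectrumKernelParams
) -> tuple[np.ndarray, np.ndarray]:
    mz = np.array([p[0] for p in spectrum.peaks], dtype=float)
    it = np.array([p[1] for p in spectrum.peaks], dtype=float)
    if params.rescale_intensity and it.size and it.max() > 0:
        it = it / it.max()
    return mz, it


def _ppk_raw(
    mz_a: np.ndarray,
    it_a: np.ndarray,
    mz_b: np.ndarray,
    it_b: np.ndarray,
    params: SpectrumKernelParams,
) -> float:
    """Unnormalised PPK between two peak arrays (integral of mixture product)."""
    if mz_a.size == 0 or mz_b.size == 0:
        return 0.0
    dmz = mz_a[:, None] - mz_b[None, :]
    dit = it_a[:, None] - it_b[None, :]
    z = np.exp(
        -(dmz**2) / (4.0 * params.sigma_mz**2) - (dit**2) / (4.0 * params.sigma_int**2)
    )
    const = 1.0 / (4.0 * np.pi * params.sigma_mz * params.sigma_int)
    return const * z.sum() / (mz_a.size * mz_b.size)


def ppk(
    spec_a: Spectrum, spec_b: Spectrum, params: SpectrumKernelParams | None = None
) -> float:
    """Probability Product Kernel between two spectra.

    Each spectrum is modelled as a uniform mixture of axis-aligned 2-D
    Gaussians centred at its (m/z, intensity) peaks with variances
    (sigma_mz^2, sigma_int^2); the kernel is the integral over the plane of
    the product of the two mixture densities.  With ``normalise`` the value
    is cosine-normalised so identical spectra score 1.  Spectra with an empty
    peak list score 0.
    """
    params = params or SpectrumKernelParams()
    a = _peak_arrays(spec_a, params)
    b = _peak_arrays(spec_b, params)
    raw = _ppk_raw(*a, *b, params)
    if not params.normalise:
        return raw
    if raw == 0.0:
        return 0.0
    denom = np.sqrt(_ppk_raw(*a, *a, params) * _ppk_raw(*b, *b, params))
    return float(raw / denom) if denom > 0 else 0.0


def _gram(
    prepped: Sequence[tuple[np.ndarray, np.ndarray]], params: SpectrumKernelParams
) -> np.ndarray:
    n = len(prepped)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = _ppk_raw(*prepped[i], *prepped[j], params)
    return K


# ---------------------------------------------------------------------------
# model


@dataclass
class IOKRModel:
    """Trained kernel ridge map from spectra to fingerprint space.

    Built with :meth:`fit` (or the module-level :func:`fit_iokr`).  Stores the
    training spectra, the training fingerprint matrix Y, the (optionally
    normalised) Gram matrix, the dual coefficients C solving
    ``(K + lambda I) C = Y``, and the pooled, sorted training peak list used
    to filter query spectra.
    """

    training_spectra: list[Spectrum]
    training_fingerprints: np.ndarray
    gram: np.ndarray
    dual: np.ndarray
    lambda_reg: float
    kernel_params: SpectrumKernelParams
    reference_peaks: np.ndarray
    _self_ppk: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _prepped: list = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_train(self) -> int:
        return len(self.training_spectra)

    @property
    def n_bits(self) -> int:
        return self.training_fingerprints.shape[1]

    @classmethod
    def fit(
        cls,
        training_pairs: Sequence[tuple[Spectrum, FingerprintVector]],
        params: SpectrumKernelParams | None = None,
        lambda_reg: float = 1e-3,
    ) -> "IOKRModel":
        """Fit the ridge system on paired (spectrum, fingerprint) data.

        Deterministic given its inputs.  Requires at least two pairs and a
        consistent fingerprint length; with ``lambda_reg = 0`` and duplicate
        spectra the system is singular and an error advises ``lambda_reg > 0``.
        """
        params = params or SpectrumKernelParams()
        if len(training_pairs) < 2:
            raise ValueError("IOKR needs at least 2 training pairs")
        lengths = {len(fp) for _, fp in training_pairs}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
        if lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")

        spectra = [s for s, _ in training_pairs]
        Y = np.stack([fp.to_array() for _, fp in training_pairs])
        reference_peaks = np.unique(
            np.concatenate([[p[0] for p in s.peaks] for s in spectra])
        )
        prepped = [_peak_arrays(s, params) for s in spectra]
        K = _gram(prepped, params)
        self_ppk = np.diag(K).copy()
        if params.normalise:
            d = np.sqrt(self_ppk)
            d[d == 0] = 1.0
            K = K / np.outer(d, d)
        try:
            dual = np.linalg.solve(K + lambda_reg * np.eye(len(spectra)), Y)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular kernel system (duplicate spectra with lambda_reg=0?); "
                "use lambda_reg > 0"
            ) from exc
        return cls(
            training_spectra=spectra,
            training_fingerprints=Y,
            gram=K,
            dual=dual,
            lambda_reg=lambda_reg,
            kernel_params=params,
            reference_peaks=reference_peaks,
            _self_ppk=self_ppk,
            _prepped=prepped,
        )

    def _ensure_prepped(self) -> None:
        if self._prepped is None:
            self._prepped = [
                _peak_arrays(s, self.kernel_params) for s in self.training_spectra
            ]
            self._self_ppk = np.array(
                [_ppk_raw(*p, *p, self.kernel_params) for p in self._prepped]
            )

    def kernel_vector(self, spectrum: Spectrum) -> np.ndarray:
        """Kernel values between a (filtered) query spectrum and the training set."""
        self._ensure_prepped()
        p = self.kernel_params
        filtered = filter_peaks(spectrum, self.reference_peaks, p.peak_match_tol)
        if not filtered.peaks:
            warnings.warn(
                f"spectrum {spectrum.id!r} has no peaks matching the training "
                "data; IOKR score is 0",
                stacklevel=2,
            )
            return np.zeros(self.n_train)
        q = _peak_arrays(filtered, p)
        k = np.array([_ppk_raw(*q, *t, p) for t in self._prepped])
        if p.normalise:
            self_q = _ppk_raw(*q, *q, p)
            denom = np.sqrt(self_q * self._self_ppk)
            denom[denom == 0] = 1.0
            k = k / denom
        return k

    def predict_fingerprint(self, spectrum: Spectrum) -> np.ndarray:
        """h(x): the predicted (real-valued) fingerprint for a spectrum."""
        return self.kernel_vector(spectrum) @ self.dual

    def save(self, path) -> None:
        """Serialise to a single .npz archive with a format-version tag."""
        p = self.kernel_params
        np.savez_compressed(
            path,
            format_version=MODEL_FORMAT_VERSION,
            fingerprints=self.training_fingerprints,
            gram=self.gram,
            dual=self.dual,
            lambda_reg=self.lambda_reg,
            reference_peaks=self.reference_peaks,
            kernel_params=json.dumps(
                {
                    "sigma_mz": p.sigma_mz,
                    "sigma_int": p.sigma_int,
                    "normalise": p.normalise,
                    "peak_match_tol": p.peak_match_tol,
                    "rescale_intensity": p.rescale_intensity,
                }
            ),
            spectra=json.dumps(
                [
                    {
                        "id": s.id,
                        "peaks": list(map(list, s.peaks)),
                        "precursor_mz": s.precursor_mz,
                    }
                    for s in self.training_spectra
                ]
            ),
        )

    @classmethod
    def load(cls, path) -> "IOKRModel":
        with np.load(path, allow_pickle=False) as z:
            version = int(z["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ValueError(f"unsupported model format version {version}")
            spectra = [
                Spectrum(
                    id=d["id"],
                    peaks=tuple(map(tuple, d["peaks"])),
                    precursor_mz=d["precursor_mz"],
                )
                for d in json.loads(str(z["spectra"]))
            ]
            return cls(
                training_spectra=spectra,
                training_fingerprints=z["fingerprints"],
                gram=z["gram"],
                dual=z["dual"],
                lambda_reg=float(z["lambda_reg"]),
                kernel_params=SpectrumKernelParams(**json.loads(str(z["kernel_params"]))),
                reference_peaks=z["reference_peaks"],
            )


def fit_iokr(
    training_pairs: Sequence[tuple[Spectrum, FingerprintVector]],
    params: SpectrumKernelParams | None = None,
    lambda_reg: float = 1e-3,
) -> IOKRModel:
    """Fit an :class:`IOKRModel`; see :meth:`IOKRModel.fit`."""
    return IOKRModel.fit(training_pairs, params, lambda_reg)


# ---------------------------------------------------------------------------
# scoring


def score_pair(
    model: IOKRModel, spectrum: Spectrum, candidate_fp: FingerprintVector
) -> float:
    """<h(x), phi(y)>: the IOKR score of one spectrum-structure pair."""
    if len(candidate_fp) != model.n_bits:
        raise ValueError(
            f"fingerprint length {len(candidate_fp)} does not match model "
            f"({model.n_bits})"
        )
    return float(model.predict_fingerprint(spectrum) @ candidate_fp.to_array())


def predict_fingerprint(model: IOKRModel, spectrum: Spectrum) -> np.ndarray:
    return model.predict_fingerprint(spectrum)


def rank_candidates(
    model: IOKRModel,
    spectrum: Spectrum,
    candidates: Sequence[tuple[str, FingerprintVector]],
) -> list[RankedCandidate]:
    """Score a candidate set and return it ordered best-first.

    Descending by score, ties broken by structure key (ascending) so the
    ordering is deterministic.  Ranks are 1-based positions in that ordering.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    h = model.predict_fingerprint(spectrum)
    scored = [(key, float(h @ fp.to_array())) for key, fp in candidates]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return [
        RankedCandidate(key=key, score=score, rank=i + 1)
        for i, (key, score) in enumerate(scored)
    ]


def rank_of(ranked: Sequence[RankedCandidate], true_keys: Iterable[str]) -> int:
    """Best (smallest) 1-based rank attained by any of the true structures."""
    keys = set(true_keys)
    hits = [rc.rank for rc in ranked if rc.key in keys]
    if not hits:
        raise KeyError(f"none of {sorted(keys)} present in the ranked list")
    return min(hits)


def aggregate_gcf_mf(
    model: IOKRModel,
    bgc_fingerprints: Mapping[str, Sequence[tuple[str, FingerprintVector]]],
    spectra: Sequence[Spectrum],
) -> LinkScore | None:
    """Best BGC-spectrum IOKR score across a GCF-MF link.

    ``bgc_fingerprints`` maps each BGC id in the gene cluster family to its
    candidate-structure fingerprints (a BGC with several structures
    contributes each separately).  Returns ``None`` — an *undefined* score,
    deliberately distinct from 0 — when no BGC carries a structure.
    """
    pairs = [
        (bgc_id, key, fp)
        for bgc_id in sorted(bgc_fingerprints)
        for key, fp in bgc_fingerprints[bgc_id]
    ]
    if not pairs or not spectra:
        return None
    best: tuple[float, str, str] | None = None
    for spec in spectra:
        h = model.predict_fingerprint(spec)
        for bgc_id, _key, fp in pairs:
            val = float(h @ fp.to_array())
            if best is None or val > best[0]:
                best = (val, spec.id, bgc_id)
    assert best is not None
    return LinkScore(value=best[0], argmax_pair=(best[1], best[2]))


def topn_curve(
    model: IOKRModel,
    test_pairs: Sequence[tuple[Spectrum, Iterable[str]]],
    candidates: Sequence[tuple[str, FingerprintVector]],
) -> tuple[np.ndarray, float]:
    """Top-n accuracy curve over n = 1..#candidates, and its normalised AUC.

    Each test pair supplies a spectrum and the keys of its true structures;
    a spectrum counts as a hit at n when its best-ranking true structure is
    within the top n.  The returned curve is non-decreasing and ends at 1.0;
    AUC is the mean of the curve (area normalised to [0, 1]).
    """
    n_cand = len(candidates)
    ranks = [
        rank_of(rank_candidates(model, spec, candidates), keys)
        for spec, keys in test_pairs
    ]
    curve = np.array(
        [np.mean([r <= n for r in ranks]) for n in range(1, n_cand + 1)]
    )
    return curve, float(curve.mean())


def score_link_table(
    model: IOKRModel,
    table,
    gcf_structures: Mapping[str, Sequence[tuple[str, str, FingerprintVector]]],
    mf_spectra: Mapping[str, Sequence[Spectrum]],
) -> np.ndarray:
    """IOKR score column aligned with a (gcf_id, mf_id) score table.

    ``gcf_structures`` maps GCF ids to (bgc_id, structure_key, fingerprint)
    triples; ``mf_spectra`` maps MF ids to member spectra.  Each row gets the
    max-aggregated BGC-spectrum score, or NaN where the link is undefined
    (no structure-annotated BGC, or no spectra).  Fingerprint predictions are
    cached per spectrum, so cost scales with #spectra + #table rows.
    """
    pred: dict[str, np.ndarray] = {}
    for mf_id, specs in mf_spectra.items():
        for spec in specs:
            if spec.id not in pred:
                pred[spec.id] = model.predict_fingerprint(spec)
    fp_mat: dict[str, np.ndarray | None] = {}
    for gcf_id, triples in gcf_structures.items():
        fp_mat[gcf_id] = (
            np.stack([fp.to_array() for _, _, fp in triples]) if triples else None
        )
    out = np.full(len(table), np.nan)
    for i, (gcf_id, mf_id) in enumerate(zip(table["gcf_id"], table["mf_id"])):
        F = fp_mat.get(gcf_id)
        specs = mf_spectra.get(mf_id, ())
        if F is None or not len(specs):
            continue
        out[i] = max(float((F @ pred[s.id]).max()) for s in specs)
    return out


def bgc_rank(
    ranked: Sequence[RankedCandidate],
    true_keys: Iterable[str],
    bgc_map: Mapping[str, Iterable[str]],
) -> int:
    """1-based rank of the true BGC implied by a metabolite ranking.

    Counts the BGCs associated with any metabolite ranked strictly better
    than the best-ranking true metabolite (ties are not counted against the
    true structure), plus one.
    """
    best = rank_of(ranked, true_keys)
    best_score = next(rc.score for rc in ranked if rc.rank == best)
    better_bgcs: set[str] = set()
    for rc in ranked:
        if rc.score > best_score:
            better_bgcs.update(bgc_map.get(rc.key, ()))
    return len(better_bgcs) + 1
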