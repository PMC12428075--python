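"""Semi-synthetic multi-annotator label simulation with cluster-wise SNR noise.

Annotator behavior is made non-stationary by partitioning the input space
into pseudo-contextual clusters (2-D projection + k-means) and assigning each
annotator a per-cluster signal-to-noise ratio in dB.  A simulated annotation
is the ground truth plus zero-mean Gaussian noise whose variance follows

    sigma^2 = P_signal / 10**(SNR_dB / 10),

with the signal power taken as the global variance of the standardized
ground truth, so an annotator's dB level means the same thing in every
cluster.  The default profile has five annotators over four clusters: one
uniform 10 dB expert, three annotators with localized competence, and one
uniformly noisy -3 dB rater; cells only described qualitatively default to
-3 dB and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data import MultiAnnotatorDataset

#: Annotator x cluster SNR (dB): expert, three localized raters, one noisy rater.
DEFAULT_SNR_DB = np.array(
    [
        [10.0, 10.0, 10.0, 10.0],
        [6.0, -3.0, -3.0, 7.0],
        [-3.0, -3.0, 8.0, -3.0],
        [-3.0, 7.0, 4.0, -3.0],
        [-3.0, -3.0, -3.0, -3.0],
    ]
)


@dataclass
class SNRProfile:
    """Annotator-by-cluster signal-to-noise matrix in decibels."""

    snr_db: np.ndarray = field(default_factory=lambda: DEFAULT_SNR_DB.copy())

    def __post_init__(self) -> None:
        self.snr_db = np.atleast_2d(np.asarray(self.snr_db, dtype=float))
        if not np.all(np.isfinite(self.snr_db)):
            raise ValueError("SNR entries must be finite")

    @property
    def n_annotators(self) -> int:
        return self.snr_db.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.snr_db.shape[1]

    def variances(self, signal_power: float = 1.0) -> np.ndarray:
        return snr_to_variance(self.snr_db, signal_power)


def snr_to_variance(snr_db, signal_power: float):
    """Noise variance implied by an SNR in dB: signal_power / 10**(snr/10)."""
    if signal_power <= 0:
        raise ValueError("signal_power must be strictly positive")
    return signal_power / 10.0 ** (np.asarray(snr_db, dtype=float) / 10.0)


def partition_inputs(X: np.ndarray, C: int, seed: int, projection: str = "pca") -> np.ndarray:
    """Pseudo-contextual clusters: standardize, project to 2-D, k-means.

    ``projection="pca"`` (default) uses the first two principal components and
    is fully deterministic; ``"umap"`` uses a neighborhood-preserving UMAP
    embedding when the optional dependency is available.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if C > X.shape[0]:
        raise ValueError("more clusters than samples")
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    if Xs.shape[1] <= 2:
        emb = Xs
    elif projection == "pca":
        emb = PCA(n_components=2, random_state=seed).fit_transform(Xs)
    elif projection == "umap":
        import umap

        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(Xs)
    else:
        raise ValueError(f"unknown projection backend {projection!r}")
    km = KMeans(n_clusters=C, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def simulate_annotations(y: np.ndarray, clusters: np.ndarray, profile: SNRProfile,
                         seed: int, signal_power: float | None = None) -> np.ndarray:
    """Corrupt ground truth with annotator- and cluster-specific Gaussian noise."""
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters, dtype=int)
    if clusters.max(initial=0) >= profile.n_clusters:
        raise ValueError("cluster label exceeds profile cluster count")
    if signal_power is None:
        signal_power = float(np.var(y))
    var = profile.variances(signal_power)  # (R, C)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((y.size, profile.n_annotators))
    sd = np.sqrt(var[:, clusters].T)  # (N, R)
    return y[:, None] + noise * sd


@dataclass
class SimulatedTask:
    """A fully provenanced synthetic crowd-regression task."""

    features: np.ndarray
    ground_truth: np.ndarray
    clusters: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    profile: SNRProfile
    true_variances: np.ndarray  # (R, C) noise variances actually used
    seed: int

    def dataset(self) -> MultiAnnotatorDataset:
        return MultiAnnotatorDataset(
            features=self.features,
            labels=np.where(self.mask, self.labels, np.nan),
            observed_mask=self.mask,
            annotator_ids=[f"sim{r+1}" for r in range(self.labels.shape[1])],
            attribute_name="simulated",
        )


def make_synthetic_task(N: int, C: int = 4, seed: int = 0,
                        profile: SNRProfile | None = None,
                        cluster_spread: float = 0.6) -> SimulatedTask:
    """Learnable 2-feature ground truth with cluster-conditioned crowd noise.

    C cluster centers are placed on a circle of radius 2.5; points are
    Gaussian around their center (sd ``cluster_spread``).  The ground truth is
    the smooth surface ``sin(x1) + 0.5 cos(1.5 x2)`` plus a cluster-specific
    offset of ``0.3 * c``, standardized to zero mean and unit variance, so the
    SNR -> variance conversion uses signal power 1.  Labels then follow the
    SNR profile; the generating clusters and variances are retained.
    """
    if profile is None:
        profile = SNRProfile(DEFAULT_SNR_DB[:, :C] if C <= 4 else
                             np.tile(DEFAULT_SNR_DB[:, :1], (1, C)))
    if C != profile.n_clusters:
        raise ValueError("cluster count must match the SNR profile")
    if N < C:
        raise ValueError("need at least one sample per cluster")
    rng = np.random.default_rng(seed)
    ang = 2.0 * np.pi * np.arange(C) / C
    centers = 2.5 * np.column_stack([np.cos(ang), np.sin(ang)])
    clusters = rng.integers(0, C, size=N)
    X = centers[clusters] + rng.normal(0.0, cluster_spread, size=(N, 2))
    y = np.sin(X[:, 0]) + 0.5 * np.cos(1.5 * X[:, 1]) + 0.3 * clusters
    y = (y - y.mean()) / y.std()
    labels = simulate_annotations(y, clusters, profile,
                                  seed=seed + 1, signal_power=1.0)
    mask = np.ones(labels.shape, dtype=bool)
    return SimulatedTask(X, y, clusters, labels, mask, profile,
                         profile.variances(1.0), seed)


#: Default per-annotator label coverage for the sensory fixture (acidity column
#: of the label-completeness table: annotators 135, 154, 155, 160, 179).
SENSORY_COVERAGE = {"135": 0.861, "154": 0.708, "155": 0.958, "160": 0.889, "179": 0.889}

SENSORY_FEATURES = [
    ("moisture", 0.0, 200.0),
    ("fat_content", 0.0, 60.0),
    ("granulometry", 0.0, 58.0),
    ("plastic_viscosity", 0.0, 10.5),
    ("yield_stress", 0.0, 62.0),
]


def make_sensory_fixture(N: int, seed: int = 0, attribute: str = "sweetness",
                         coverage: dict[str, float] | None = None) -> MultiAnnotatorDataset:
    """Synthetic stand-in emulating the cacao sensory-panel schema.

    Five positive physicochemical features within their documented ranges,
    one 1-10 sensory attribute scored by five annotators with heterogeneous
    noise, and per-annotator missingness matching the configured coverage
    rates.  Purely synthetic: values are generated, not measured.
    """
    if N < 10:
        raise ValueError("fixture needs at least 10 samples")
    coverage = coverage or SENSORY_COVERAGE
    rng = np.random.default_rng(seed)
    cols = {}
    for name, lo, hi in SENSORY_FEATURES:
        cols[name] = lo + (hi - lo) * rng.beta(2.0, 3.5, size=N)
    X = np.column_stack(list(cols.values()))
    # latent 1-10 attribute: smooth in standardized features
    Xs = (X - X.mean(0)) / X.std(0)
    latent = 5.5 + 1.6 * np.tanh(Xs[:, 1]) - 1.1 * np.tanh(Xs[:, 0]) + 0.6 * np.sin(Xs[:, 2])
    ids = list(coverage.keys())
    noise_sd = np.linspace(0.5, 1.4, len(ids))
    Y = latent[:, None] + rng.standard_normal((N, len(ids))) * noise_sd
    Y = np.clip(Y, 1.0, 10.0)
    mask = rng.random((N, len(ids))) < np.array([coverage[a] for a in ids])
    # every row keeps at least one annotation
    empty = ~mask.any(axis=1)
    if empty.any():
        mask[empty, rng.integers(0, len(ids), size=int(empty.sum()))] = True
    return MultiAnnotatorDataset(
        features=X,
        labels=np.where(mask, Y, np.nan),
        observed_mask=mask,
        feature_names=[n for n, _, _ in SENSORY_FEATURES],
        annotator_ids=ids,
        attribute_name=attribute,
    )
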