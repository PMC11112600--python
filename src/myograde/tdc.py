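"""TDC: refinement of the 5 clinical strength grades into 25 sub-levels.

The procedure follows five steps: (a) build an autoencoder whose encoder is
the Tcnformer feature extractor (through the 560-dim feature, classification
head removed) followed by a linear latent map, and whose decoder is a fully
connected stack reconstructing the flattened 4x200 segment; (b) pretrain it
under the mean squared reconstruction loss L_rec = (1/N) sum ||x_i - xhat_i||^2;
(c) for each coarse grade independently, initialize K=5 cluster centres by
K-means on the latent codes and then jointly descend
L = L_rec + lambda * KL(P || Q), where Q are student-t soft assignments around
the centres and P is the sharpened target distribution; (d) read off hard
sub-cluster labels and order the sub-clusters within each grade by the mean
RMS amplitude of their member segments, yielding fractional grades
g.0, g.2, ..., g.8; (e) freeze the feature extractor of the supervised
classifier and fine-tune a fresh 25-class head on the refined labels.

With the calibrated defaults (latent 160, decoder 160->209->800, 5 centres)
the full model has exactly 299,601 trainable parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .io import SegmentSet, ValidationError
from .tcnformer import TcnformerConfig, TcnformerModel

__all__ = [
    "TdcConfig",
    "Autoencoder",
    "TdcModel",
    "FineGrade",
    "GradeClusterState",
    "ClusterState",
    "reconstruction_loss",
    "soft_assign",
    "target_distribution",
    "clustering_loss",
    "kl_gradients",
    "pretrain_autoencoder",
    "tdc_train",
    "assign_fine_labels",
    "fine_class_index",
    "finetune_25",
    "predict_fine",
]

KL_EPS = 1e-10


@dataclass
class TdcConfig:
    d_z: int = 160
    decoder_hidden: int = 209
    alpha: float = 1.0            # student-t degrees of freedom
    lam: float = 0.1              # clustering-loss weight
    metric_dim: int = 10          # whitened subspace used by the cluster
    #                               kernel (the canonical deep-embedded-
    #                               clustering working dimensionality)
    k_sub: int = 5                # sub-clusters per coarse grade
    kmeans_restarts: int = 20
    p_refresh: int = 5            # epochs between target-distribution updates
    label_tol: float = 1e-3       # stop when < 0.1% of hard labels change
    smooth_neighbors: bool = True  # average each code with its adjacent
    #                                overlapping windows of the same
    #                                recording before clustering (the
    #                                sub-level varies slowly in time)
    pretrain_epochs: int = 100
    epochs: int = 80              # joint-loss epochs per grade
    lr: float = 1e-4
    batch_size: int = 72
    head_lr: float = 1e-3         # 25-class head fine-tuning
    head_epochs: int = 200
    seed: int = 0


@dataclass(frozen=True)
class FineGrade:
    """A refined grade: coarse clinical grade plus within-grade sub-index."""

    coarse: int
    sub: int

    def __post_init__(self) -> None:
        if self.coarse not in range(1, 6) or self.sub not in range(5):
            raise ValidationError(
                f"invalid fine grade ({self.coarse}, {self.sub})")

    @property
    def fractional(self) -> float:
        return self.coarse + 0.2 * self.sub

    def __str__(self) -> str:
        return f"{self.fractional:.1f}"


def fine_class_index(fg: FineGrade) -> int:
    """0-based 25-class index: (coarse-1)*5 + sub."""
    return (fg.coarse - 1) * 5 + fg.sub


def fine_from_index(idx: int) -> FineGrade:
    return FineGrade(coarse=idx // 5 + 1, sub=idx % 5)


class Autoencoder:
    """Tcnformer-encoder autoencoder.

    ``encoder`` is a TcnformerModel whose classification head is unused; only
    the front-end parameters count.  ``latent`` maps the 560-dim feature to
    the d_z-dim hidden variable z; the decoder reconstructs the flattened
    800-sample segment.
    """

    def __init__(self, cfg: TdcConfig,
                 encoder: TcnformerModel | None = None,
                 encoder_cfg: TcnformerConfig | None = None) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAE])
                                    .generate_state(1)[0])
        if encoder is None:
            encoder = TcnformerModel(encoder_cfg or TcnformerConfig(seed=cfg.seed))
        else:
            # deep copy so autoencoder training never mutates the classifier
            src = encoder
            encoder = TcnformerModel(src.cfg)
            encoder.set_state(src.get_state())
        self.encoder = encoder
        d_feat = encoder.cfg.feature_dim
        d_in = encoder.cfg.n_channels * encoder.cfg.seq_len
        self.latent = nn.Dense(d_feat, cfg.d_z, rng, name="latent")
        self.dec1 = nn.Dense(cfg.d_z, cfg.decoder_hidden, rng, name="dec1")
        self.dec_relu = nn.ReLU()
        self.dec2 = nn.Dense(cfg.decoder_hidden, d_in, rng, name="dec2")
        self.d_in = d_in

    def params(self) -> list[nn.Param]:
        return (self.encoder.front_params() + self.latent.params()
                + self.dec1.params() + self.dec2.params())

    def get_state(self) -> dict[str, np.ndarray]:
        state = self.encoder.get_state()
        for p in (self.latent.params() + self.dec1.params()
                  + self.dec2.params()):
            state[p.name] = p.value.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        self.encoder.set_state({k: v for k, v in state.items()
                                if not k.startswith(("latent", "dec"))})
        for p in (self.latent.params() + self.dec1.params()
                  + self.dec2.params()):
            p.value[...] = state[p.name]

    def clone(self) -> "Autoencoder":
        other = Autoencoder(self.cfg, encoder=TcnformerModel(self.encoder.cfg))
        other.set_state(self.get_state())
        for mine, theirs in zip(self.params(), other.params()):
            theirs.trainable = mine.trainable
        return other

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        feat = self.encoder.feature(x, train=train)
        return self.latent.forward(feat, train=train)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.dec_relu.forward(self.dec1.forward(z, train), train)
        return self.dec2.forward(h, train)

    def reconstruct(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.decode(self.encode(x, train), train)

    def backward_decoder(self, dxhat: np.ndarray) -> np.ndarray:
        return self.dec1.backward(self.dec_relu.backward(self.dec2.backward(dxhat)))

    def backward_encoder(self, dz: np.ndarray) -> np.ndarray:
        return self.encoder.backward_feature(self.latent.backward(dz))

    def encode_batched(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        return np.concatenate([self.encode(x[i:i + batch])
                               for i in range(0, len(x), batch)])


class TdcModel:
    """Autoencoder plus K trainable cluster centres (one coarse grade)."""

    def __init__(self, autoencoder: Autoencoder, centers: np.ndarray) -> None:
        self.autoencoder = autoencoder
        self.centers = nn.Param(np.asarray(centers, dtype=np.float64),
                                name="centers")

    def params(self) -> list[nn.Param]:
        return self.autoencoder.params() + [self.centers]


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """L_rec = (1/N) sum_i ||x_i - xhat_i||^2 over flattened segments.

    Returns the loss and its gradient with respect to ``xhat``.
    """
    xf = x.reshape(len(x), -1)
    diff = xhat - xf
    loss = float(np.mean(np.sum(diff ** 2, axis=1)))
    return loss, 2.0 * diff / len(x)


def soft_assign(z: np.ndarray, centers: np.ndarray,
                alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignment q_ij of latent codes to cluster centres."""
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite latent codes")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d2 = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    f = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return f / f.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target p_ij = (q_ij^2 / f_j) / sum_k (q_ik^2 / f_k)
    with f_j = sum_i q_ij the soft cluster mass."""
    mass = Q.sum(axis=0)
    if np.any(mass <= 0):
        raise ValidationError(
            f"cluster(s) {np.where(mass <= 0)[0].tolist()} have zero soft mass")
    W = Q ** 2 / mass
    return W / W.sum(axis=1, keepdims=True)


def clustering_loss(P: np.ndarray, Q: np.ndarray, eps: float = KL_EPS) -> float:
    """KL(P || Q) = sum_ij p_ij log(p_ij / q_ij), floored at ``eps``."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], eps))))


def kl_gradients(z: np.ndarray, centers: np.ndarray, P: np.ndarray,
                 alpha: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of KL(P || Q(z, centers)) w.r.t. z and the centres.

    dL/dz_i   =  (alpha+1)/alpha * sum_j (1+||z_i-mu_j||^2/alpha)^-1 (p_ij-q_ij)(z_i-mu_j)
    dL/dmu_j  = -(alpha+1)/alpha * sum_i (1+||z_i-mu_j||^2/alpha)^-1 (p_ij-q_ij)(z_i-mu_j)
    """
    diff = z[:, None, :] - centers[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    inv = 1.0 / (1.0 + d2 / alpha)
    f = inv ** ((alpha + 1.0) / 2.0)
    Q = f / f.sum(axis=1, keepdims=True)
    w = (alpha + 1.0) / alpha * inv * (P - Q)      # (N, K)
    dz = np.einsum("nk,nkd->nd", w, diff, optimize=True)
    dmu = -np.einsum("nk,nkd->kd", w, diff, optimize=True)
    return dz, dmu


def pretrain_autoencoder(segs: SegmentSet, cfg: TdcConfig | None = None,
                         encoder: TcnformerModel | None = None,
                         epochs: int | None = None,
                         verbose: bool = False) -> tuple[Autoencoder, dict]:
    """Step (b): fit the autoencoder under the reconstruction loss.

    ``encoder`` transfers the trained supervised feature extractor
    (recommended); when omitted a freshly initialized encoder is used.

    With a transferred encoder the feature extractor stays frozen during this
    warm-up — it already carries the learned representation, and letting the
    reconstruction objective rewrite it erodes the discriminative geometry
    the clustering step depends on.  The latent map is initialised with the
    principal components of the encoder features over ``segs`` (the optimal
    linear reconstruction subspace), then refined with the decoder.
    """
    cfg = cfg or TdcConfig()
    if len(segs) == 0:
        raise ValidationError("cannot pretrain on an empty segment set")
    ae = Autoencoder(cfg, encoder=encoder)
    transferred = encoder is not None
    if transferred:
        # the transferred feature extractor already carries the learned
        # representation; the latent map is set to a random *orthonormal*
        # projection (an isometry of the feature space, so the latent
        # geometry mirrors the feature geometry) and the warm-up fits the
        # decoder to this fixed code
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x15])
                                    .generate_state(1)[0])
        G = rng.standard_normal((ae.latent.W.value.shape[0], cfg.d_z))
        Qmat, _ = np.linalg.qr(G)
        ae.latent.W.value[...] = Qmat[:, :cfg.d_z]
        if ae.latent.b is not None:
            ae.latent.b.value[...] = 0.0
        for p in ae.encoder.front_params() + ae.latent.params():
            p.trainable = False
    epochs = cfg.pretrain_epochs if epochs is None else epochs
    opt = nn.Adam(ae.params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 11)
    X = segs.data
    history = {"rec_loss": []}
    for epoch in range(epochs):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = X[idx]
            # transferred encoders are frozen: keep their normalisation
            # statistics fixed by encoding in eval mode
            z = ae.encode(xb, train=not transferred)
            xhat = ae.decode(z, train=True)
            loss, dxhat = reconstruction_loss(xb, xhat)
            opt.zero_grad()
            dz = ae.backward_decoder(dxhat)
            ae.backward_encoder(dz)
            opt.step()
            losses.append(loss)
        history["rec_loss"].append(float(np.mean(losses)))
        if verbose and epoch % 10 == 0:
            print(f"pretrain epoch {epoch:4d}  L_rec {history['rec_loss'][-1]:.5f}")
    return ae, history


@dataclass
class GradeClusterState:
    """Converged per-grade clustering: centres, soft/target assignments,
    hard within-grade labels and the indices of the member segments."""

    grade: int
    model: TdcModel
    indices: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    hard: np.ndarray
    loss_trajectory: list = field(default_factory=list)
    converged: bool = False


@dataclass
class ClusterState:
    """Clustering of the full segment set: one GradeClusterState per grade."""

    grades: dict[int, GradeClusterState] = field(default_factory=dict)
    alpha: float = 1.0
    lam: float = 0.1

    def hard_sublabels(self, n: int) -> np.ndarray:
        out = np.full(n, -1, dtype=np.int64)
        for st in self.grades.values():
            out[st.indices] = st.hard
        return out


def _neighbor_smooth(z: np.ndarray, subjects: np.ndarray | None,
                     starts: np.ndarray | None) -> np.ndarray:
    """Average each latent code with its temporally adjacent windows from the
    same recording (window of 3).  Overlapping windows are noisy views of a
    slowly varying contraction state; smoothing reduces estimator noise
    without mixing recordings."""
    if subjects is None or starts is None:
        return z
    out = z.copy()
    subjects = subjects.astype(str)
    for s in np.unique(subjects):
        rows = np.where(subjects == s)[0]
        order = rows[np.argsort(starts[rows])]
        block = z[order]
        sm = block.copy()
        if len(block) > 1:
            sm[1:-1] = (block[:-2] + block[1:-1] + block[2:]) / 3.0
            sm[0] = (block[0] + block[1]) / 2.0
            sm[-1] = (block[-2] + block[-1]) / 2.0
        out[order] = sm
    return out


def _fit_grade(ae: Autoencoder, X: np.ndarray, idx: np.ndarray, grade: int,
               cfg: TdcConfig, verbose: bool = False,
               subjects: np.ndarray | None = None,
               starts: np.ndarray | None = None) -> GradeClusterState:
    """Cluster one grade's segments in its latent codes.

    The student-t kernel and K-means operate in a per-grade *whitened*
    latent frame (top ``metric_dim`` principal components of the grade's
    codes, frozen after pretraining): an isotropic Euclidean kernel on the
    raw 160-d codes is dominated by reconstruction-salient nuisance
    directions, while the planted structure is low-dimensional.  Cluster
    centres remain parameters of the original latent space.
    """
    K = cfg.k_sub
    if len(idx) < K:
        raise ValidationError(
            f"grade {grade} has {len(idx)} segments; cannot form {K} sub-clusters")
    model_ae = ae.clone()
    Xg = X[idx]

    def encode_all():
        zz = model_ae.encode_batched(Xg)
        if cfg.smooth_neighbors:
            zz = _neighbor_smooth(zz, subjects, starts)
        return zz

    z = encode_all()
    from sklearn.decomposition import PCA
    m = min(cfg.metric_dim, z.shape[1], len(z) - 1)
    pca = PCA(n_components=m, random_state=cfg.seed)
    pca.fit(z)
    # frozen whitening map A: (m, d_z); to_s(v) = (v - mean) A^T
    A = pca.components_ / np.sqrt(pca.explained_variance_ + 1e-12)[:, None]

    def to_s(v):
        return (v - pca.mean_) @ A.T

    km = KMeans(n_clusters=K, n_init=cfg.kmeans_restarts,
                random_state=cfg.seed + grade)
    km.fit(to_s(z))
    # lift whitened centres back into the full latent space
    lift = np.sqrt(pca.explained_variance_ + 1e-12)[:, None] * pca.components_
    model = TdcModel(model_ae, pca.mean_ + km.cluster_centers_ @ lift)
    # autoencoder weights use Adam; the centres take plain gradient steps so
    # their movement is proportional to the (weak) clustering gradient
    opt = nn.Adam(model_ae.params(), lr=cfg.lr)
    opt_mu = nn.SGD([model.centers], lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 100 + grade)
    Q = soft_assign(to_s(z), to_s(model.centers.value), cfg.alpha)
    P = target_distribution(Q)
    hard_prev = Q.argmax(axis=1)
    traj: list[float] = []
    converged = False
    min_size = max(2, len(Xg) // (K * 4))  # cluster-death guard
    snapshot = (model_ae.get_state(), model.centers.value.copy())
    for epoch in range(cfg.epochs):
        if epoch % cfg.p_refresh == 0:
            z = encode_all()
            Q = soft_assign(to_s(z), to_s(model.centers.value), cfg.alpha)
            P = target_distribution(Q)
            hard = Q.argmax(axis=1)
            sizes = np.bincount(hard, minlength=K)
            if sizes.min() < min_size:
                # the KL sharpening is starving a sub-cluster: roll back to
                # the last healthy refresh and stop (standard degeneration
                # guard for self-training clustering)
                model_ae.set_state(snapshot[0])
                model.centers.value[...] = snapshot[1]
                break
            snapshot = (model_ae.get_state(), model.centers.value.copy())
            xhat = model_ae.decode(z)
            rec, _ = reconstruction_loss(Xg, xhat)
            kl = clustering_loss(P, Q) / len(Xg)
            traj.append(rec + cfg.lam * kl)
            if verbose:
                print(f"grade {grade} epoch {epoch:3d} "
                      f"L {traj[-1]:.5f} (rec {rec:.5f} kl {kl:.5f})")
            if epoch > 0:
                change = float(np.mean(hard != hard_prev))
                if change < cfg.label_tol:
                    converged = True
                    hard_prev = hard
                    break
            hard_prev = hard
        order = rng.permutation(len(Xg))
        for i in range(0, len(Xg), cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            xb = Xg[b]
            # eval-mode encoding: the frozen feature extractor's batch-norm
            # running statistics must not drift between target refreshes
            zb = model_ae.encode(xb, train=False)
            xhat = model_ae.decode(zb, train=True)
            _, dxhat = reconstruction_loss(xb, xhat)
            dz_rec = model_ae.backward_decoder(dxhat)
            dzs, dmus = kl_gradients(to_s(zb), to_s(model.centers.value),
                                     P[b], cfg.alpha)
            opt.zero_grad()
            opt_mu.zero_grad()
            model.centers.grad += cfg.lam * (dmus @ A) / len(b)
            model_ae.backward_encoder(dz_rec + cfg.lam * (dzs @ A) / len(b))
            opt.step()
            opt_mu.step()
    z = encode_all()
    Q = soft_assign(to_s(z), to_s(model.centers.value), cfg.alpha)
    P = target_distribution(Q)
    return GradeClusterState(grade=grade, model=model, indices=idx, Q=Q, P=P,
                             hard=Q.argmax(axis=1), loss_trajectory=traj,
                             converged=converged)


def tdc_train(segs: SegmentSet, coarse_labels: np.ndarray | None = None,
              cfg: TdcConfig | None = None,
              autoencoder: Autoencoder | None = None,
              verbose: bool = False) -> tuple[Autoencoder, ClusterState]:
    """Step (c): per-grade K-means initialization followed by joint descent of
    the reconstruction + lambda * KL objective on encoder, decoder and centres.

    Returns the (shared, pretrained) autoencoder and the converged cluster
    state; each grade keeps its own fine-tuned copy of the autoencoder inside
    its :class:`GradeClusterState`.
    """
    cfg = cfg or TdcConfig()
    labels = np.asarray(segs.labels if coarse_labels is None else coarse_labels)
    if labels is None or len(labels) != len(segs):
        raise ValidationError("per-segment coarse labels are required")
    if autoencoder is None:
        autoencoder, _ = pretrain_autoencoder(segs, cfg)
    state = ClusterState(alpha=cfg.alpha, lam=cfg.lam)
    for grade in np.unique(labels):
        idx = np.where(labels == grade)[0]
        state.grades[int(grade)] = _fit_grade(
            autoencoder, segs.data, idx, int(grade), cfg, verbose=verbose,
            subjects=(None if segs.subject_ids is None
                      else segs.subject_ids[idx]),
            starts=None if segs.starts is None else segs.starts[idx])
    return autoencoder, state


def assign_fine_labels(state: ClusterState, coarse_labels: np.ndarray,
                       segment_rms: np.ndarray) -> list[FineGrade]:
    """Step (d): map sub-clusters to sub-indices 0..4 ordered by the mean RMS
    amplitude (of the filtered, un-normalized segments) of their members, so
    the fractional grade increases with contraction strength within a grade."""
    coarse_labels = np.asarray(coarse_labels)
    segment_rms = np.asarray(segment_rms, dtype=np.float64)
    fine: list[FineGrade | None] = [None] * len(coarse_labels)
    for grade, st in state.grades.items():
        K = st.Q.shape[1]
        means = np.full(K, np.nan)
        for k in range(K):
            members = st.indices[st.hard == k]
            if len(members):
                means[k] = segment_rms[members].mean()
        empty = np.where(np.isnan(means))[0]
        if len(empty):
            warnings.warn(
                f"grade {grade}: empty sub-cluster(s) {empty.tolist()}; "
                "relabeling with the remaining clusters", stacklevel=2)
        order = np.argsort(means)  # NaNs (empty clusters) sort last
        sub_of_cluster = np.empty(K, dtype=np.int64)
        rank = 0
        for k in order:
            sub_of_cluster[k] = min(rank, 4)
            if not np.isnan(means[k]):
                rank += 1
        for i, k in zip(st.indices, st.hard):
            fine[i] = FineGrade(coarse=int(grade), sub=int(sub_of_cluster[k]))
    missing = [i for i, f in enumerate(fine) if f is None]
    if missing:
        raise ValidationError(f"segments {missing[:5]}... have no cluster state")
    return fine  # type: ignore[return-value]


def finetune_25(model: TcnformerModel, segs: SegmentSet,
                fine_labels, cfg: TdcConfig | None = None,
                val_fraction: float = 0.2,
                verbose: bool = False) -> tuple[TcnformerModel, dict]:
    """Step (e): freeze the feature extractor, train a fresh 256/64/25 head.

    Features are extracted once in eval mode (the frozen front end, including
    batch-norm statistics, is bit-identical before and after).  The hold-out
    is a stratified segment-level split.  Returns the 25-class model and a
    history dict with ``val_acc``.
    """
    cfg = cfg or TdcConfig()
    if fine_labels and isinstance(fine_labels[0], FineGrade):
        y = np.array([fine_class_index(f) for f in fine_labels], dtype=np.int64)
    else:
        y = np.asarray(fine_labels, dtype=np.int64)
    if y.min() < 0 or y.max() > 24:
        raise ValidationError("fine labels must be 25-class indices 0..24 "
                              "or FineGrade instances")
    feats = np.concatenate([model.feature(segs.data[i:i + 256])
                            for i in range(0, len(segs), 256)])
    rng = np.random.default_rng(cfg.seed + 17)
    val_mask = np.zeros(len(y), dtype=bool)
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    tr, va = np.where(~val_mask)[0], np.where(val_mask)[0]

    new = TcnformerModel(TcnformerConfig(
        **{**model.cfg.__dict__, "n_classes": 25}))
    front_state = model.get_state()
    new.set_state({**new.get_state(),
                   **{k: v for k, v in front_state.items()
                      if not k.startswith(("fc", "out"))}})
    new.freeze_front()
    head = new.head
    drop_rng = np.random.default_rng(cfg.seed + 23)
    for lay in head.layers:
        if isinstance(lay, nn.Dropout):
            lay.rng = drop_rng
    opt = nn.Adam(head.params(), lr=cfg.head_lr)
    history = {"loss": [], "val_acc": []}
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.head_epochs):
        order = rng.permutation(len(tr))
        losses = []
        for i in range(0, len(tr), cfg.batch_size):
            b = tr[order[i:i + cfg.batch_size]]
            probs = nn.softmax(head.forward(feats[b], train=True))
            loss, dlogits = nn.cross_entropy(probs, y[b])
            opt.zero_grad()
            head.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_pred = nn.softmax(head.forward(feats[va])).argmax(axis=1)
        acc = float((val_pred == y[va]).mean())
        history["loss"].append(float(np.mean(losses)))
        history["val_acc"].append(acc)
        if acc > best_acc:
            best_acc = acc
            best_state = [p.value.copy() for p in head.params()]
        if verbose and epoch % 20 == 0:
            print(f"head epoch {epoch:4d}  loss {history['loss'][-1]:.4f}  "
                  f"val {acc:.3f}")
    if best_state is not None:
        for p, v in zip(head.params(), best_state):
            p.value[...] = v
    history["best_val_acc"] = best_acc
    return new, history


def predict_fine(model25: TcnformerModel, segs: SegmentSet) -> list[FineGrade]:
    """Per-segment fractional grade from a 25-class model."""
    probs = np.concatenate([model25.forward(segs.data[i:i + 256])
                            for i in range(0, len(segs), 256)])
    return [fine_from_index(int(i)) for i in probs.argmax(axis=1)]
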