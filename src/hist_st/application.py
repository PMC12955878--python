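"""Downstream clinical heads on predicted expression grids.

A ConvNeXt-V2-style convolutional backbone consumes a gene x height x width
expression grid: a 4x4/stride-4 stem with layer normalization, four stages
of residual blocks (depthwise 7x7 convolution, layer normalization, a
pointwise expansion, GELU, global response normalization, pointwise
projection, plus a drop-path-regularized identity), separated by
2x2/stride-2 downsampling, then global average pooling, layer normalization
and a linear embedding.

Heads:

* survival — the embedding is concatenated with one-hot encoded clinical
  covariates and passed through two linear layers to a scalar risk.  Training
  minimizes the negative Cox partial likelihood on L2-normalized batch risks;
  the default restricts each event's denominator to its risk set
  (subjects with t_j >= t_i, Breslow handling of ties), with an
  ``as_printed`` mode whose denominator sums over the whole batch.
* immunotherapy response — a single linear layer to two-class probabilities,
  trained with cross-entropy.

Cohorts are split by stratified k-fold (k = 5) preserving the
censored/uncensored proportion; survival training uses AdamW at lr 5e-3 for
300 epochs with the whole training set as one batch, response training uses
AdamW at lr 5e-5 for 200 epochs at batch size 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .grid import ExpressionGrid
from .nn.tensor import Tensor

__all__ = [
    "AppNetSpec", "SurvivalRecord", "RiskOutput", "CategoricalEncoder",
    "GRN", "ConvNeXtV2Block", "ConvNeXtV2Backbone",
    "SurvivalModel", "ICBModel",
    "cox_loss", "stratified_kfold", "pseudo_bulk",
    "train_survival", "predict_risk", "train_icb", "predict_icb",
    "cross_validate_survival", "cross_validate_icb",
]


@dataclass
class AppNetSpec:
    """Backbone configuration for the application network."""

    in_channels: int
    stage_depths: tuple[int, ...] = (2, 2, 6, 2)
    stage_widths: tuple[int, ...] = (40, 80, 160, 320)
    embed_dim: int = 64
    expansion: int = 4
    dw_kernel: int = 7
    drop_path: float = 0.0
    head_hidden: int = 32

    def __post_init__(self):
        if len(self.stage_depths) != len(self.stage_widths):
            raise ValueError("stage_depths and stage_widths must align")
        if any(b <= a for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValueError("stage widths must be increasing")


@dataclass
class SurvivalRecord:
    """Overall-survival observation: time, event flag, clinical covariates."""

    time: float
    event: int  # 1 uncensored (event observed), 0 censored
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("survival time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class RiskOutput:
    risk: np.ndarray          # L2-normalized risk per sample
    group: np.ndarray         # "high" / "low" after median split

    def __post_init__(self):
        self.risk = np.asarray(self.risk, dtype=np.float64)


class CategoricalEncoder:
    """One-hot encoder with an explicit slot for unseen categories.

    Categories are learned from the training folds only; any category not
    seen at fit time maps to the per-field ``unknown`` slot at inference.
    """

    def __init__(self):
        self.categories_: dict[str, list[str]] | None = None

    def fit(self, records: Sequence[SurvivalRecord]) -> "CategoricalEncoder":
        fields = sorted({k for r in records for k in r.covariates})
        self.categories_ = {
            f: sorted({str(r.covariates.get(f, "")) for r in records})
            for f in fields
        }
        return self

    @property
    def width(self) -> int:
        if self.categories_ is None:
            raise RuntimeError("encoder is not fitted")
        return sum(len(v) + 1 for v in self.categories_.values())  # +1 unknown

    def transform(self, records: Sequence[SurvivalRecord]) -> np.ndarray:
        if self.categories_ is None:
            raise RuntimeError("encoder is not fitted")
        out = np.zeros((len(records), self.width), dtype=np.float32)
        for i, r in enumerate(records):
            offset = 0
            for f, cats in self.categories_.items():
                val = str(r.covariates.get(f, ""))
                idx = cats.index(val) if val in cats else len(cats)  # unknown slot
                out[i, offset + idx] = 1.0
                offset += len(cats) + 1
        return out

    def to_dict(self) -> dict:
        return {"categories": self.categories_}

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalEncoder":
        enc = cls()
        enc.categories_ = d["categories"]
        return enc


# ---------------------------------------------------------------------------
# backbone


class GRN(nn.Module):
    """Global response normalization: channel competition via spatial norms.

    gx_c = ||x_c||_2 over the spatial grid, nx_c = gx_c / mean_c(gx_c),
    out = gamma * x * nx + beta + x, with gamma and beta zero-initialized.
    """

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = nn.Parameter(np.zeros(channels))
        self.beta = nn.Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x):
        c = x.shape[1]
        gx = ((x * x).sum(axis=(2, 3), keepdims=True) + self.eps) ** 0.5
        nx = gx / (gx.mean(axis=1, keepdims=True) + self.eps)
        shape = (1, c, 1, 1)
        return self.gamma.reshape(shape) * (x * nx) + self.beta.reshape(shape) + x


class ConvNeXtV2Block(nn.Module):
    """Residual block: DWConv7x7 -> LN -> PWConv (expand) -> GELU -> GRN ->
    PWConv (project), plus the drop-path-scaled identity."""

    def __init__(self, channels: int, expansion: int = 4, dw_kernel: int = 7,
                 drop_path: float = 0.0, *, rng):
        super().__init__()
        hidden = expansion * channels
        self.dwconv = nn.Conv2d(channels, channels, dw_kernel,
                                padding=dw_kernel // 2, groups=channels, rng=rng)
        self.norm = nn.LayerNorm2d(channels)
        self.pwconv1 = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.grn = GRN(hidden)
        self.pwconv2 = nn.Conv2d(hidden, channels, 1, rng=rng)
        self.drop_path = drop_path
        self._droprng = np.random.default_rng(int(rng.integers(2 ** 31)))

    def forward(self, x):
        y = self.pwconv2(self.grn(self.pwconv1(self.norm(self.dwconv(x))).gelu()))
        if self.training and self.drop_path > 0.0:
            keep = (self._droprng.random(x.shape[0]) >= self.drop_path)
            scale = keep.astype(np.float32) / (1.0 - self.drop_path)
            y = y * Tensor(scale.reshape(-1, 1, 1, 1))
        return y + x


class ConvNeXtV2Backbone(nn.Module):
    """Stem, four (configurable) stages with downsampling, pooled embedding."""

    def __init__(self, spec: AppNetSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.stage_widths
        self.stem = nn.Conv2d(spec.in_channels, w[0], 4, stride=4, rng=rng)
        self.stem_norm = nn.LayerNorm2d(w[0])
        self.downs = nn.ModuleList()
        self.stages = nn.ModuleList()
        for si, (depth, width) in enumerate(zip(spec.stage_depths, w)):
            if si > 0:
                self.downs.append(nn.Sequential(
                    nn.LayerNorm2d(w[si - 1]),
                    nn.Conv2d(w[si - 1], width, 2, stride=2, rng=rng)))
            self.stages.append(nn.Sequential(*[
                ConvNeXtV2Block(width, spec.expansion, spec.dw_kernel,
                                spec.drop_path, rng=rng)
                for _ in range(depth)]))
        self.final_norm = nn.LayerNorm(w[-1])
        self.embed = nn.Linear(w[-1], spec.embed_dim, rng=rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape((1,) + tuple(x.shape))
        y = self.stem_norm(self.stem(x))
        for si, stage in enumerate(self.stages):
            if si > 0:
                y = self.downs[si - 1](y)
            y = stage(y)
        pooled = y.mean(axis=(2, 3))                # global average pooling
        return self.embed(self.final_norm(pooled))  # (N, embed_dim)


class SurvivalModel(nn.Module):
    """Backbone embedding + one-hot covariates -> two linear layers -> risk."""

    def __init__(self, spec: AppNetSpec, n_covariates: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 7)
        self.backbone = ConvNeXtV2Backbone(spec, seed=seed)
        self.fc1 = nn.Linear(spec.embed_dim + n_covariates, spec.head_hidden, rng=rng)
        self.fc2 = nn.Linear(spec.head_hidden, 1, rng=rng)

    def forward(self, grids, covariates: np.ndarray) -> Tensor:
        feats = self.backbone(grids)
        cat = nn.concat([feats, Tensor(np.asarray(covariates, dtype=np.float32))],
                        axis=1)
        return self.fc2(self.fc1(cat).relu()).reshape(-1)


class ICBModel(nn.Module):
    """Backbone embedding -> single linear layer -> two-class logits."""

    def __init__(self, spec: AppNetSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 11)
        self.backbone = ConvNeXtV2Backbone(spec, seed=seed)
        self.fc = nn.Linear(spec.embed_dim, 2, rng=rng)

    def forward(self, grids) -> Tensor:
        return self.fc(self.backbone(grids))


# ---------------------------------------------------------------------------
# Cox partial likelihood


def l2_normalize_risks(risks: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((risks * risks).sum() + eps) ** 0.5
    return risks / norm


def cox_loss(risks, times, events,
             mode: Literal["risk_set", "as_printed"] = "risk_set",
             l2_normalize: bool = True):
    """Negative Cox partial likelihood averaged over uncensored samples.

    ``risk_set`` restricts each event's denominator to subjects still at
    risk (t_j >= t_i; ties share the full tied risk set — Breslow);
    ``as_printed`` sums the denominator over the whole batch regardless of
    time.  Risks are first L2-normalized across the batch.  Accepts a numpy
    array (returns a float) or an autograd tensor (returns a scalar tensor
    for training).
    """
    is_tensor = isinstance(risks, Tensor)
    r = risks if is_tensor else Tensor(np.asarray(risks, dtype=np.float64))
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events)
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    d = int(events.sum())
    if d == 0:
        raise ValueError("Cox loss undefined: no uncensored samples in the batch")
    if l2_normalize:
        r = l2_normalize_risks(r)
    out = _cox_core(r, times, events.astype(np.float64), mode)
    return out if is_tensor else float(out.item())


def _cox_core(r: Tensor, times: np.ndarray, events: np.ndarray,
              mode: str) -> Tensor:
    n = r.data.shape[0]
    if mode == "risk_set":
        at_risk = times[None, :] >= times[:, None]  # (i, j): j in risk set of i
    elif mode == "as_printed":
        at_risk = np.ones((n, n), dtype=bool)
    else:
        raise ValueError(f"unknown cox loss mode {mode!r}")
    rd = r.data.astype(np.float64)
    d = events.sum()
    shift = rd.max()
    e = np.exp(rd - shift)
    s = at_risk @ e                      # sum_{j in R_i} exp(r_j - shift)
    log_denom = np.log(s) + shift
    loss = -(events * (rd - log_denom)).sum() / d

    def bw(g):
        # dL/dr_k = -(1/d) [ e_k - sum_{i event} 1[k in R_i] e^{r_k} / S_i ]
        w = (events / s) @ at_risk       # sum over events i with k in R_i of 1/S_i
        grad = -(events - w * e) / d
        r._accum(g * grad.astype(r.data.dtype))

    return Tensor._result(np.array(loss, dtype=rd.dtype), (r,), bw)


# ---------------------------------------------------------------------------
# protocol helpers


def stratified_kfold(events: Sequence[int] | Sequence[SurvivalRecord],
                     k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Fold membership preserving the censored/uncensored proportion.

    Returns a list of k test-index arrays (pairwise disjoint, covering all
    samples, sizes differing by at most one).
    """
    if len(events) and isinstance(events[0], SurvivalRecord):
        strata = np.array([r.event for r in events])
    else:
        strata = np.asarray(events)
    n = len(strata)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    counts = np.bincount(strata.astype(int))
    if (counts < k).any():
        import warnings
        warnings.warn("a stratum has fewer members than folds; "
                      "proportions will be best-effort")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(n), strata)]


def pseudo_bulk(grid: ExpressionGrid) -> dict[str, float]:
    """Per-gene mean over valid cells — slide-level pseudo-RNA-seq profile."""
    if not grid.validity.any():
        raise ValueError("pseudo-bulk undefined: grid has no valid cells")
    means = grid.values[:, grid.validity].mean(axis=1)
    return dict(zip(grid.gene_names, means.astype(float)))


# ---------------------------------------------------------------------------
# training loops


def _stack_grids(grids) -> np.ndarray:
    arrs = [g.values if isinstance(g, ExpressionGrid) else np.asarray(g, dtype=np.float32)
            for g in grids]
    return np.stack(arrs).astype(np.float32)


def train_survival(grids, records: Sequence[SurvivalRecord], spec: AppNetSpec,
                   epochs: int = 300, lr: float = 5e-3,
                   weight_decay: float = 1e-4, seed: int = 0,
                   mode: Literal["risk_set", "as_printed"] = "risk_set",
                   encoder: CategoricalEncoder | None = None):
    """Train the survival head; the whole training set is one batch."""
    xs = _stack_grids(grids)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    if events.sum() == 0:
        raise ValueError("training set has no uncensored samples")
    if encoder is None:
        encoder = CategoricalEncoder().fit(records)
    cov = encoder.transform(records)
    model = SurvivalModel(spec, n_covariates=cov.shape[1], seed=seed)
    opt = nn.AdamW(model.parameters(), lr=lr, betas=(0.9, 0.999),
                   weight_decay=weight_decay)
    losses = []
    model.train()
    for _ in range(epochs):
        risks = model(xs, cov)
        loss = cox_loss(risks, times, events, mode=mode)
        if not np.isfinite(loss.item()):
            raise RuntimeError("non-finite Cox loss; aborting")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return model, encoder, losses


def predict_risk(model: SurvivalModel, grids, records: Sequence[SurvivalRecord],
                 encoder: CategoricalEncoder) -> RiskOutput:
    xs = _stack_grids(grids)
    cov = encoder.transform(records)
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            risks = model(xs, cov).data.astype(np.float64)
    finally:
        model.train(was_training)
    norm = np.sqrt((risks ** 2).sum()) or 1.0
    risks = risks / norm
    med = np.median(risks)
    group = np.where(risks > med, "high", "low")  # ties go to low
    return RiskOutput(risk=risks, group=group)


def train_icb(grids, labels: Sequence[int], spec: AppNetSpec,
              epochs: int = 200, lr: float = 5e-5, batch_size: int = 20,
              weight_decay: float = 1e-4, seed: int = 0):
    """Train the response classifier (labels: 1 responder, 0 non-responder)."""
    xs = _stack_grids(grids)
    ys = np.asarray(labels, dtype=np.int64)
    if len(np.unique(ys)) < 2:
        raise ValueError("training labels contain a single class")
    model = ICBModel(spec, seed=seed)
    opt = nn.AdamW(model.parameters(), lr=lr, betas=(0.9, 0.999),
                   weight_decay=weight_decay)
    rng = np.random.default_rng(seed + 3)
    losses = []
    model.train()
    for _ in range(epochs):
        order = rng.permutation(len(ys))
        total, batches = 0.0, 0
        for s in range(0, len(ys), batch_size):
            idx = order[s:s + batch_size]
            logits = model(xs[idx])
            loss = nn.cross_entropy_logits(logits, ys[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            batches += 1
        losses.append(total / batches)
    return model, losses


def predict_icb(model: ICBModel, grids) -> np.ndarray:
    """Class probabilities (n, 2), columns (non-responder, responder)."""
    xs = _stack_grids(grids)
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            logits = model(xs).data
    finally:
        model.train(was_training)
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


def cross_validate_survival(grids, records: Sequence[SurvivalRecord],
                            spec: AppNetSpec, k: int = 5, seed: int = 0,
                            **train_kwargs):
    """Stratified k-fold survival training; held-out risks per sample.

    Returns (risks, fold_of): risks aligned with the input order, each
    predicted by the model of the fold that held that sample out.
    """
    folds = stratified_kfold(records, k=k, seed=seed)
    n = len(records)
    risks = np.zeros(n)
    fold_of = np.zeros(n, dtype=int)
    for fi, test in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test)
        model, enc, _ = train_survival(
            [grids[i] for i in train_idx], [records[i] for i in train_idx],
            spec, seed=seed + fi, **train_kwargs)
        out = predict_risk(model, [grids[i] for i in test],
                           [records[i] for i in test], enc)
        risks[test] = out.risk
        fold_of[test] = fi
    return risks, fold_of


def cross_validate_icb(grids, labels, spec: AppNetSpec, k: int = 5,
                       seed: int = 0, **train_kwargs):
    """Stratified k-fold response prediction; held-out probabilities."""
    ys = np.asarray(labels, dtype=int)
    folds = stratified_kfold(ys, k=k, seed=seed)
    probs = np.zeros((len(ys), 2))
    for fi, test in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(ys)), test)
        model, _ = train_icb([grids[i] for i in train_idx], ys[train_idx],
                             spec, seed=seed + fi, **train_kwargs)
        probs[test] = predict_icb(model, [grids[i] for i in test])
    return probs
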