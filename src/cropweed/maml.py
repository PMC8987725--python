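"""Model-agnostic meta-learning (MAML) for 6-way few-shot classification.

The engine is generic over any differentiable model exposing

* ``loss_and_grad(theta, X, y) -> (loss, flat gradient)``
* ``accuracy(theta, X, y) -> float`` (for evaluation)

so the same inner/outer loop drives the 9-layer CNN (``nn.build_meta_cnn``)
and the scalar analytic models used to verify the meta-gradient.

Inner loop (per task): theta_i' = theta - alpha * grad L_support(theta);
outer loop: theta <- theta - beta * grad_theta sum_i L_query(theta_i').
With ``first_order=True`` the adaptation Jacobian is dropped (theta_i'
treated as constant w.r.t. theta); the exact second-order gradient
(I - alpha H_support) grad L_query is available via a central-difference
Hessian-vector product, which is exact for quadratic losses.

Episode conventions follow standard n-way k-shot usage: a "6-shot" episode
carries 5 support + 1 query sample per class, a "2-shot" episode 1 + 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synthetic import LabeledPatchSet, N_CLASSES

__all__ = ["MetaTask", "MAMLConfig", "cross_entropy", "inner_adapt",
           "meta_update", "sample_task", "meta_train", "evaluate_few_shot",
           "shots_to_counts"]


def shots_to_counts(shots: int) -> tuple[int, int]:
    """Map the benchmark's episode naming to (k_support, k_query) per class:
    6-shot -> (5, 1), 2-shot -> (1, 1)."""
    if shots < 2:
        raise ValueError("shots must be >= 2 (support + query)")
    return shots - 1, 1


@dataclasses.dataclass
class MetaTask:
    """One n-way episode: disjoint support (inner loop) and query (outer
    loop) samples covering every class."""

    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray

    def __post_init__(self):
        if len(self.support_x) == 0:
            raise ValueError("support set must be non-empty")


@dataclasses.dataclass(frozen=True)
class MAMLConfig:
    alpha: float = 0.1  # inner (adaptation) step size
    beta: float = 0.01  # outer (meta) step size (applied to the task-summed gradient)
    k_support: int = 5
    k_query: int = 1
    n_tasks: int = 4  # tasks per meta-batch
    meta_iterations: int = 9600
    inner_steps: int = 1
    first_order: bool = True
    grad_clip: float = 10.0  # global-norm cap on the outer gradient; 0 disables
    seed: int = 0
    eval_interval: int = 10

    def __post_init__(self):
        if self.alpha <= 0 or self.beta < 0:
            raise ValueError("alpha must be > 0 and beta >= 0")
        if self.k_support < 1 or self.k_query < 1:
            raise ValueError("k_support and k_query must be >= 1")


def cross_entropy(predictions: np.ndarray, labels: np.ndarray,
                  reduction: str = "mean") -> float:
    """Categorical cross-entropy -sum(y * log p) over probability rows.

    ``predictions`` holds probability vectors (rows must sum to 1 within
    1e-6); ``labels`` is one-hot.  Zero iff every prediction puts all mass
    on its true class; for two classes this reduces to the familiar binary
    form y log p + (1-y) log(1-p) up to sign.
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=np.float64))
    y = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if p.shape != y.shape:
        raise ValueError("predictions/labels shape mismatch")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("prediction rows must sum to 1 (tolerance 1e-6)")
    per_sample = -np.sum(y * np.log(np.clip(p, 1e-300, None)), axis=1)
    if reduction == "mean":
        return float(per_sample.mean())
    if reduction == "sum":
        return float(per_sample.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def inner_adapt(model, theta: np.ndarray, task: MetaTask, alpha: float,
                steps: int = 1) -> np.ndarray:
    """Task adaptation: gradient step(s) on the support loss.

    Returns a new parameter vector; ``theta`` itself is never mutated.
    """
    theta_i = np.array(theta, copy=True)
    for _ in range(steps):
        loss, grad = model.loss_and_grad(theta_i, task.support_x, task.support_y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite support gradient during adaptation")
        theta_i = theta_i - alpha * grad
    return theta_i


def _second_order_task_grad(model, theta, theta_i, task, alpha):
    """(I - alpha H_support(theta)) @ grad L_query(theta_i'), with the
    Hessian-vector product by central differences on the support gradient
    (exact for quadratic losses)."""
    _, g_query = model.loss_and_grad(theta_i, task.query_x, task.query_y)
    v = g_query
    vn = np.linalg.norm(v)
    if vn == 0:
        return g_query
    eps = 1e-4 * max(1.0, np.linalg.norm(theta)) / vn
    _, g_plus = model.loss_and_grad(theta + eps * v, task.support_x, task.support_y)
    _, g_minus = model.loss_and_grad(theta - eps * v, task.support_x, task.support_y)
    hvp = (g_plus - g_minus) / (2.0 * eps)
    return g_query - alpha * hvp


def meta_update(model, theta: np.ndarray, tasks: list[MetaTask],
                adapted: list[np.ndarray], cfg: MAMLConfig) -> np.ndarray:
    """Outer-loop step: theta <- theta - beta * sum_i grad L_query_i(theta_i').

    With ``cfg.first_order`` the query gradients at the adapted parameters
    are summed directly; otherwise each task contributes the exact composite
    gradient through its adaptation step.
    """
    if len(tasks) != len(adapted):
        raise ValueError("one adapted parameter vector per task required")
    total = np.zeros_like(theta)
    for task, theta_i in zip(tasks, adapted):
        if cfg.first_order:
            _, g = model.loss_and_grad(theta_i, task.query_x, task.query_y)
        else:
            g = _second_order_task_grad(model, theta, theta_i, task, cfg.alpha)
        total += g
    if cfg.grad_clip:
        norm = np.linalg.norm(total)
        if norm > cfg.grad_clip:
            total *= cfg.grad_clip / norm
    return theta - cfg.beta * total


def sample_task(dataset: LabeledPatchSet, k_support: int, k_query: int,
                rng: np.random.Generator) -> MetaTask:
    """Draw a 6-way episode with k_support + k_query samples per class,
    support and query disjoint."""
    hist = dataset.class_histogram()
    need = k_support + k_query
    if np.any(hist < need):
        raise ValueError(
            f"need >= {need} samples per class, have {hist.tolist()}"
        )
    sup_idx, qry_idx = [], []
    for c in range(N_CLASSES):
        pool = np.flatnonzero(dataset.labels == c)
        pick = rng.choice(pool, size=need, replace=False)
        sup_idx.extend(pick[:k_support])
        qry_idx.extend(pick[k_support:])
    sup = np.asarray(sup_idx)
    qry = np.asarray(qry_idx)
    return MetaTask(
        support_x=dataset.patches[sup], support_y=dataset.labels[sup],
        query_x=dataset.patches[qry], query_y=dataset.labels[qry],
    )


def meta_train(dataset: LabeledPatchSet, model, cfg: MAMLConfig,
               theta0: np.ndarray | None = None):
    """Full MAML loop; returns (theta, curve) where ``curve`` is the mean
    post-adaptation query accuracy of the meta-batch, recorded every
    ``cfg.eval_interval`` outer iterations (list of (iteration, accuracy)).

    Deterministic given ``cfg.seed``; aborts with the iteration index if the
    loss diverges.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = model.init_params(rng) if theta0 is None else np.array(theta0, copy=True)
    curve = []
    for it in range(cfg.meta_iterations):
        tasks = [sample_task(dataset, cfg.k_support, cfg.k_query, rng)
                 for _ in range(cfg.n_tasks)]
        adapted = [inner_adapt(model, theta, t, cfg.alpha, cfg.inner_steps)
                   for t in tasks]
        if cfg.eval_interval and it % cfg.eval_interval == 0:
            acc = float(np.mean([
                model.accuracy(th, t.query_x, t.query_y)
                for th, t in zip(adapted, tasks)
            ]))
            curve.append((it, acc))
        theta = meta_update(model, theta, tasks, adapted, cfg)
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"meta-training diverged at iteration {it}")
    return theta, curve


def evaluate_few_shot(model, theta: np.ndarray, dataset: LabeledPatchSet,
                      cfg: MAMLConfig, n_episodes: int,
                      rng: np.random.Generator | int | None = 0):
    """Few-shot test protocol: per episode, adapt on the support set and
    score on the query set.  Returns (mean accuracy, standard deviation)
    over ``n_episodes`` episodes."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    accs = []
    for _ in range(n_episodes):
        task = sample_task(dataset, cfg.k_support, cfg.k_query, rng)
        theta_i = inner_adapt(model, theta, task, cfg.alpha, cfg.inner_steps)
        accs.append(model.accuracy(theta_i, task.query_x, task.query_y))
    return float(np.mean(accs)), float(np.std(accs))
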