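"""AICc multi-model averaging with natural-average and zero methods.

All nested sub-models of a maximal fixed-effect structure are
enumerated under marginality (an interaction enters only together with
both of its main effects), fitted by ML, and weighted by Akaike weights
``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`` with
``Delta_i = AICc_i - min AICc``.

Per-term outputs:

* RVI — relative variable importance, the summed weight of models
  containing the term;
* natural average — weighted mean over models containing the term,
  weights renormalized over that subset (avoids shrinkage to zero);
* zero method — weighted mean over all models with absent terms
  contributing zero, so ``estimate_zero = estimate_natural * RVI``
  identically;
* unconditional SE — the revised Burnham-Anderson form
  ``sum_i w_i * sqrt(se_i^2 + (beta_i - beta_bar)^2)``;
* the conditional rule for main effects involved in interactions: if an
  interaction is significant in the full-set average, its mains are
  re-averaged only over models where the interaction is itself (Wald)
  significant; if it is not, the mains are averaged over models lacking
  the interaction plus models where it is non-significant.

P-values are two-sided normal on estimate / unconditional SE.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_models import FittedModel, LMMWorkspace, ModelSpec, fit_glmm_binomial, fit_lm

MAX_BASE_TERMS = 20


def parents(term: str) -> tuple[str, ...]:
    """Main effects an interaction term depends on (itself if a main)."""
    return tuple(term.split(":"))


def enumerate_models(
    base_terms: tuple[str, ...] | list[str], max_models: int | None = 100_000
) -> list[tuple[str, ...]]:
    """All fixed-term subsets obeying marginality, including the null model.

    Subsets keep the base ordering; the intercept-only model is the
    empty tuple.
    """
    base = tuple(base_terms)
    if len(base) > MAX_BASE_TERMS:
        raise ValueError(f"{len(base)} terms exceed the {MAX_BASE_TERMS}-term guard")
    if len(set(base)) != len(base):
        raise ValueError("duplicate terms in base specification")
    out = []
    for mask in itertools.product((False, True), repeat=len(base)):
        sub = tuple(t for t, m in zip(base, mask) if m)
        have = set(sub)
        if all((":" not in t) or all(p in have for p in parents(t)) for t in sub):
            out.append(sub)
    if max_models is not None and len(out) > max_models:
        raise ValueError(
            f"{len(out)} admissible models exceed the cap of {max_models}; reduce the term set"
        )
    return out


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights from a vector of AICc values (min-shifted for stability)."""
    a = np.asarray(aiccs, float)
    if a.size == 0:
        raise ValueError("empty AICc vector")
    if not np.isfinite(a).all():
        raise ValueError("non-finite AICc values")
    w = np.exp(-(a - a.min()) / 2.0)
    return w / w.sum()


@dataclass
class ModelSet:
    """A fitted candidate-model set with Akaike weights."""

    base_terms: tuple[str, ...]
    members: list[FittedModel]
    weights: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.weights is None:
            self.weights = akaike_weights([m.aicc for m in self.members])
        self.weights = np.asarray(self.weights, float)

    def contains(self, term: str) -> np.ndarray:
        return np.array([term in m.beta for m in self.members])

    def ledger(self) -> pd.DataFrame:
        """Per-member audit table: terms, logLik, k, AICc, delta, weight."""
        a = np.array([m.aicc for m in self.members])
        return pd.DataFrame(dict(
            terms=[" + ".join(m.spec.fixed_terms) or "(intercept only)" for m in self.members],
            loglik=[m.loglik for m in self.members],
            k=[m.k for m in self.members],
            n=[m.n for m in self.members],
            aicc=a, delta=a - a.min(), weight=self.weights,
        )).sort_values("delta").reset_index(drop=True)


def fit_model_set(
    data: pd.DataFrame, base_spec: ModelSpec, max_models: int | None = 100_000,
    n_nodes: int = 15,
) -> ModelSet:
    """Enumerate and fit every admissible nested model of ``base_spec``.

    Gaussian models share one cached-Gram workspace; non-converged
    members are dropped with a warning and the weights renormalized.
    """
    subsets = enumerate_models(base_spec.fixed_terms, max_models=max_models)
    members: list[FittedModel] = []
    if base_spec.family == "gaussian" and base_spec.random_groups:
        ws = LMMWorkspace(data, base_spec.response, base_spec.fixed_terms,
                          base_spec.random_groups)
        for sub in subsets:
            members.append(ws.fit(sub))
    elif base_spec.family == "gaussian":
        for sub in subsets:
            members.append(fit_lm(data, ModelSpec(base_spec.response, sub)))
    else:
        for sub in subsets:
            members.append(fit_glmm_binomial(
                data, ModelSpec(base_spec.response, sub, base_spec.random_groups,
                                "binomial"), n_nodes=n_nodes))
    bad = [m for m in members if not m.converged]
    if bad:
        warnings.warn(
            f"dropping {len(bad)} non-converged member(s) from the model set", stacklevel=2)
        members = [m for m in members if m.converged]
    if not members:
        raise RuntimeError("no converged members in the model set")
    return ModelSet(tuple(base_spec.fixed_terms), members)


# ---------------------------------------------------------------------------
# averaging


def rvi(model_set: ModelSet, term: str) -> float:
    """Relative variable importance: summed weight of models containing *term*."""
    if term not in model_set.base_terms and term != "(Intercept)":
        raise ValueError(f"unknown term {term!r}")
    return float(model_set.weights[model_set.contains(term)].sum())


def _weighted_average(members, weights, term) -> tuple[float, float]:
    w = np.asarray(weights, float)
    w = w / w.sum()
    b = np.array([m.beta[term] for m in members])
    s = np.array([m.se[term] for m in members])
    est = float(w @ b)
    se = float(w @ np.sqrt(s**2 + (b - est) ** 2))
    return est, se


def average_natural(model_set: ModelSet, term: str) -> tuple[float, float]:
    """Natural-average estimate and unconditional SE for one term.

    Averages only over models containing the term, weights renormalized
    over that subset.
    """
    mask = model_set.contains(term)
    if not mask.any():
        raise ValueError(f"term {term!r} appears in no member model")
    members = [m for m, keep in zip(model_set.members, mask) if keep]
    return _weighted_average(members, model_set.weights[mask], term)


def average_zero(model_set: ModelSet, term: str) -> tuple[float, float]:
    """Zero-method estimate and unconditional SE for one term.

    Models lacking the term contribute estimate 0 and SE 0 with their
    full (unrenormalized) weight, so the estimate equals the natural
    average times RVI.
    """
    mask = model_set.contains(term)
    if not mask.any():
        raise ValueError(f"term {term!r} appears in no member model")
    w = model_set.weights
    b = np.array([m.beta.get(term, 0.0) for m in model_set.members])
    s = np.array([m.se.get(term, 0.0) for m in model_set.members])
    est = float(w @ b)
    se = float(w @ np.sqrt(s**2 + (b - est) ** 2))
    return est, se


def _p_from(est: float, se: float) -> float:
    # exact (noise-free) fits leave float dust in both estimate and SE;
    # a numerically-zero estimate is null, whatever the dust SE says
    if abs(est) < 1e-8 and se < 1e-8:
        return 1.0
    if se == 0:
        return 0.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


@dataclass
class AveragingResult:
    """Per-term model-averaged estimates for one averaging method."""

    method: str
    table: pd.DataFrame  # index: term; estimate, se, z, p, rvi, selection_note

    def estimate(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _result_table(model_set: ModelSet, rows: dict[str, tuple[float, float, str]],
                  method: str) -> AveragingResult:
    recs = []
    for term, (est, se, note) in rows.items():
        recs.append(dict(term=term, estimate=est, se=se,
                         z=np.inf if se == 0 else est / se,
                         p=_p_from(est, se), rvi=rvi(model_set, term),
                         selection_note=note))
    df = pd.DataFrame(recs).set_index("term")
    return AveragingResult(method, df)


def average_all(model_set: ModelSet, method: str = "natural") -> AveragingResult:
    """Full-set average of every base term by the natural or zero method."""
    fn = {"natural": average_natural, "zero": average_zero}[method]
    rows = {}
    for term in model_set.base_terms:
        est, se = fn(model_set, term)
        rows[term] = (est, se, "all models" if method == "zero" else "models containing term")
    return _result_table(model_set, rows, method)


def conditional_average(model_set: ModelSet, alpha: float = 0.05) -> AveragingResult:
    """Natural average with the interaction-conditional model-subset rule.

    Pass 1 classifies each interaction as significant or not from the
    full-set natural average.  Pass 2 re-averages every main effect
    involved in interactions over the member subset consistent with that
    classification: for a significant interaction only members where it
    is itself Wald-significant; for a non-significant one members
    lacking it plus members where it is non-significant.  Weights are
    renormalized within each subset.  An empty subset falls back to the
    full-set average with a warning.
    """
    full = average_all(model_set, "natural")
    interactions = [t for t in model_set.base_terms if ":" in t]
    sig = {t: full.p(t) < alpha for t in interactions}

    rows: dict[str, tuple[float, float, str]] = {}
    for term in model_set.base_terms:
        involved = [i for i in interactions if i != term and term in parents(i)]
        if not involved:
            rows[term] = (full.estimate(term), full.se(term), "full set")
            continue
        keep = model_set.contains(term)
        notes = []
        for inter in involved:
            has_inter = model_set.contains(inter)
            inter_sig = np.array([
                (inter in m.beta) and (m.wald_p(inter) < alpha) for m in model_set.members])
            if sig[inter]:
                keep = keep & has_inter & inter_sig
                notes.append(f"{inter} significant in average: members with {inter} significant")
            else:
                keep = keep & (~has_inter | ~inter_sig)
                notes.append(f"{inter} not significant in average: members without it or with it non-significant")
        if not keep.any() or model_set.weights[keep].sum() < 1e-12:
            warnings.warn(
                f"conditional subset empty for {term!r}; falling back to full-set average",
                stacklevel=2)
            rows[term] = (full.estimate(term), full.se(term), "fallback: full set (empty subset)")
            continue
        members = [m for m, k in zip(model_set.members, keep) if k]
        est, se = _weighted_average(members, model_set.weights[keep], term)
        rows[term] = (est, se, "; ".join(notes) + f" (m={len(members)})")
    return _result_table(model_set, rows, "conditional")


# ---------------------------------------------------------------------------
# reporting


def build_table(
    result: AveragingResult, display_names: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Report table ordered by RVI then |estimate|, significant terms flagged."""
    df = result.table.copy()
    if df.empty:
        return pd.DataFrame(columns=["term", "estimate", "se", "p", "rvi", "significant"])
    df = df.reset_index()
    if display_names:
        def disp(t):
            return ": ".join(display_names.get(p, p) for p in t.split(":"))
        df["term"] = [disp(t) for t in df["term"]]
    df["significant"] = df["p"] < alpha
    df = df.sort_values(["rvi", "estimate"], key=lambda s: s.abs() if s.name == "estimate" else s,
                        ascending=[False, False])
    return df[["term", "estimate", "se", "p", "rvi", "significant"]].reset_index(drop=True)


def format_table(table: pd.DataFrame) -> str:
    """Fixed-width text rendering of a report table."""
    lines = [f"{'term':<55}{'estimate':>10}{'SE':>8}{'P':>8}{'RVI':>6}"]
    for _, r in table.iterrows():
        mark = "*" if r.get("significant", False) else " "
        p = "<0.001" if r["p"] < 0.001 else f"{r['p']:.3f}"
        lines.append(
            f"{r['term']:<55}{r['estimate']:>10.3f}{r['se']:>8.3f}{p:>8}{r['rvi']:>6.2f} {mark}")
    return "\n".join(lines)


def averaged_residuals(model_set: ModelSet) -> np.ndarray:
    """Weight-averaged conditional residuals across the member models."""
    return np.sum(
        [w * m.residuals for w, m in zip(model_set.weights, model_set.members)], axis=0)
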