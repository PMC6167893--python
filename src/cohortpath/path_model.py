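"""Recursive structural path model over genotype, life-course BMI and
interval diabetes diagnosis, with survey-weighted estimation.

The model is a recursive DAG on the temporally ordered nodes
G < BMI21 < D1 < BMI45 < D2 < BMI65 (BMI nodes linear, diagnosis nodes
logit, adjustment covariates entering every equation). Because the DAG has
no latent variables, the joint likelihood factorizes into node-given-parents
terms, so the survey-weighted fit decomposes into per-equation weighted GLMs
("factorized" method); under the monotone missingness created by
age-censoring this equals full-information maximum likelihood for
missing-at-random outcomes. The "fiml_mc" method additionally integrates
over continuous BMI mediators that are missing not-by-age while a descendant
is observed, via a Monte-Carlo EM with fixed common random draws.

Direct effects are edge coefficients; indirect effects are products of edge
coefficients along each directed path (linear-predictor scale, the usual SEM
convention for mixed linear/logit systems); standard errors come from the
multivariate delta method using the joint stacked-score sandwich covariance
across equations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from ._design import build_design_matrix
from .simulate import DEFAULT_COVARIATES, NODE_COLUMNS
from .survey import FitResult, SurveyDesign, SurveyGLM, taylor_variance

__all__ = [
    "PathModelSpec",
    "PathModel",
    "PathFit",
    "EffectEstimate",
    "default_path_spec",
    "fit_path_model",
    "effect_decomposition",
    "edge_odds_ratio",
    "NonConvergenceError",
]

Z95 = float(stats.norm.ppf(0.975))

CANONICAL_ORDER = ["G", "bmi21", "d1", "bmi45", "d2", "bmi65"]
CANONICAL_FAMILY = {
    "G": "exogenous",
    "bmi21": "linear",
    "d1": "logit",
    "bmi45": "linear",
    "d2": "logit",
    "bmi65": "linear",
}


class NonConvergenceError(RuntimeError):
    """An equation failed to converge; carries the node name."""

    def __init__(self, node: str, detail: str = ""):
        super().__init__(f"equation for node {node!r} did not converge. {detail}")
        self.node = node


@dataclass
class PathModelSpec:
    """Node set (with family), directed edges, covariates, estimation method.

    Nodes are listed in temporal order; every edge must run forward in that
    order (recursive/acyclic system). ``column_map`` links node names to
    cohort columns.
    """

    nodes: list[tuple[str, str]] = field(
        default_factory=lambda: [(n, CANONICAL_FAMILY[n]) for n in CANONICAL_ORDER]
    )
    edges: list[tuple[str, str]] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    method: str = "factorized"
    column_map: dict[str, str] = field(default_factory=lambda: dict(NODE_COLUMNS))

    @property
    def node_names(self) -> list[str]:
        return [n for n, _ in self.nodes]

    @property
    def families(self) -> dict[str, str]:
        return dict(self.nodes)

    def endogenous(self) -> list[str]:
        fam = self.families
        return [n for n in self.node_names if fam[n] != "exogenous"]

    def parents(self, node: str) -> list[str]:
        order = {n: i for i, n in enumerate(self.node_names)}
        return sorted((s for s, t in self.edges if t == node), key=order.get)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        names = self.node_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        order = {n: i for i, n in enumerate(names)}
        for s, t in self.edges:
            if s not in order or t not in order:
                raise ValueError(f"edge ({s}, {t}) references an undeclared node")
            if order[s] >= order[t]:
                raise ValueError(f"edge ({s}, {t}) runs against the temporal order")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("edge set contains a cycle")
        # the canonical temporal chain must not have interior gaps
        present = [n for n in CANONICAL_ORDER if n in order]
        if present:
            lo = min(CANONICAL_ORDER.index(n) for n in present)
            hi = max(CANONICAL_ORDER.index(n) for n in present)
            gap = [n for n in CANONICAL_ORDER[lo : hi + 1] if n not in order]
            if gap:
                raise ValueError(f"broken temporal chain: interior node(s) {gap} missing")
        for n, fam in self.nodes:
            if n in CANONICAL_FAMILY and fam != CANONICAL_FAMILY[n]:
                raise ValueError(
                    f"node {n!r} must have family {CANONICAL_FAMILY[n]!r}, got {fam!r}"
                )
            if fam not in ("exogenous", "linear", "logit"):
                raise ValueError(f"unknown family {fam!r} for node {n!r}")
        if self.method not in ("factorized", "fiml_mc"):
            raise ValueError("method must be 'factorized' or 'fiml_mc'")

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["nodes"] = [list(t) for t in self.nodes]
        d["edges"] = [list(t) for t in self.edges]
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str) -> "PathModelSpec":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source, encoding="utf-8") as fh:
                d = json.load(fh)
        d["nodes"] = [tuple(t) for t in d["nodes"]]
        d["edges"] = [tuple(t) for t in d["edges"]]
        return cls(**d)


def default_path_spec(
    include_d1_d2: bool = True,
    covariates: list[str] | None = None,
    method: str = "factorized",
) -> PathModelSpec:
    """The a-priori life-course DAG.

    Genotype feeds every BMI and diagnosis node directly; each BMI feeds the
    diagnosis of the immediately following period; each period's diagnosis
    feeds the next BMI; consecutive BMIs carry over. The D1->D2 temporal
    dependence edge is configurable (default on). Covariates enter every
    equation.
    """
    edges = [
        ("G", "bmi21"),
        ("G", "d1"),
        ("G", "bmi45"),
        ("G", "d2"),
        ("G", "bmi65"),
        ("bmi21", "d1"),
        ("bmi21", "bmi45"),
        ("d1", "bmi45"),
        ("bmi45", "d2"),
        ("bmi45", "bmi65"),
        ("d2", "bmi65"),
    ]
    if include_d1_d2:
        edges.insert(8, ("d1", "d2"))
    spec = PathModelSpec(
        edges=edges,
        covariates=list(covariates) if covariates is not None else list(DEFAULT_COVARIATES),
        method=method,
    )
    spec.validate()
    return spec


@dataclass
class PathFit:
    """Stacked result of the path fit: per-node equations plus joint covariance."""

    node_results: dict[str, FitResult]
    params: np.ndarray
    cov: np.ndarray
    slices: dict[str, slice]
    term_index: dict[tuple[str, str], int]  # (node, term) -> stacked position
    sigma2: dict[str, float]                # residual variance of linear nodes
    method: str
    n_missing_genotype: int
    n_by_node: dict[str, int]

    def edge_coef(self, edge: tuple[str, str]) -> tuple[float, float]:
        """(estimate, se) of an edge coefficient in the child's equation."""
        src, dst = edge
        if (dst, src) not in self.term_index:
            raise KeyError(f"edge {edge} not in fitted model")
        j = self.term_index[(dst, src)]
        return float(self.params[j]), float(np.sqrt(self.cov[j, j]))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for node, res in self.node_results.items():
            fr = res.summary_frame()
            fr.insert(0, "equation", node)
            rows.append(fr)
        return pd.concat(rows, ignore_index=True)


@dataclass
class EffectEstimate:
    """A direct, indirect or total effect on the linear-predictor scale."""

    source: str
    target: str
    kind: str                      # 'direct' | 'indirect' | 'total'
    path: list[str]
    estimate: float
    se: float
    ci: tuple[float, float]
    exponentiated: tuple[float, float, float] | None = None  # OR, CI when target is logit

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["path"] = list(self.path)
        return d


class PathModel(BaseEstimator):
    """Survey-weighted recursive path model estimator.

    Parameters
    ----------
    spec : PathModelSpec or None for the default DAG.
    method : overrides ``spec.method`` when given ('factorized' | 'fiml_mc').
    single_psu : lone-PSU-stratum policy forwarded to the variance code.
    mc_draws, mc_seed, em_max_iter, em_tol : Monte-Carlo EM controls for
        'fiml_mc' (fixed draws make the fit deterministic).

    Fitted attributes: ``result_`` (:class:`PathFit`), ``params_``, ``cov_``,
    ``node_results_``, ``n_missing_genotype_``.
    """

    def __init__(
        self,
        spec: PathModelSpec | None = None,
        method: str | None = None,
        single_psu: str = "error",
        alpha: float = 0.05,
        mc_draws: int = 64,
        mc_seed: int = 0,
        em_max_iter: int = 100,
        em_tol: float = 1e-6,
    ) -> None:
        self.spec = spec
        self.method = method
        self.single_psu = single_psu
        self.alpha = alpha
        self.mc_draws = mc_draws
        self.mc_seed = mc_seed
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol

    # ------------------------------------------------------------------
    def _node_frame(self, df: pd.DataFrame, spec: PathModelSpec) -> pd.DataFrame:
        """Data frame with one column per node (canonical names)."""
        out = {}
        for node in spec.node_names:
            col = spec.column_map.get(node, node)
            if col not in df.columns:
                raise KeyError(f"cohort lacks column {col!r} for node {node!r}")
            out[node] = pd.to_numeric(df[col]).to_numpy(dtype=float)
        return pd.DataFrame(out, index=df.index)

    def fit(self, df: pd.DataFrame, design: SurveyDesign) -> "PathModel":
        spec = self.spec if self.spec is not None else default_path_spec()
        spec.validate()
        method = self.method or spec.method
        nodes = self._node_frame(df, spec)
        Xc, cov_names = build_design_matrix(df, spec.covariates)
        cov_frame = pd.DataFrame(Xc, columns=cov_names, index=df.index)

        g = nodes["G"].to_numpy() if "G" in nodes.columns else np.zeros(len(df))
        has_g = ~np.isnan(g)
        self.n_missing_genotype_ = int((~has_g).sum())
        base_mask = has_g.copy()
        if design.subpop is not None:
            base_mask &= design.subpop

        if method == "factorized":
            fit = self._fit_factorized(nodes, cov_frame, design, base_mask, spec)
        else:
            fit = self._fit_fiml_mc(df, nodes, cov_frame, design, base_mask, spec)
        self.spec_ = spec
        self.method_ = method
        self.result_ = fit
        self.params_ = fit.params
        self.cov_ = fit.cov
        self.node_results_ = fit.node_results
        return self

    def _equation_X(
        self, node: str, nodes: pd.DataFrame, cov_frame: pd.DataFrame, spec: PathModelSpec
    ) -> pd.DataFrame:
        parents = spec.parents(node)
        X = pd.DataFrame(index=nodes.index)
        X["const"] = 1.0
        for p in parents:
            X[p] = nodes[p]
        for c in cov_frame.columns[1:]:  # skip duplicate intercept
            X[c] = cov_frame[c]
        return X

    def _fit_factorized(
        self,
        nodes: pd.DataFrame,
        cov_frame: pd.DataFrame,
        design: SurveyDesign,
        base_mask: np.ndarray,
        spec: PathModelSpec,
        weights_override: np.ndarray | None = None,
    ) -> PathFit:
        node_results: dict[str, FitResult] = {}
        slices: dict[str, slice] = {}
        term_index: dict[tuple[str, str], int] = {}
        sigma2: dict[str, float] = {}
        n_by_node: dict[str, int] = {}
        score_blocks: list[np.ndarray] = []
        B_blocks: list[np.ndarray] = []
        params_all: list[np.ndarray] = []
        pos = 0
        for node in spec.endogenous():
            fam = spec.families[node]
            X = self._equation_X(node, nodes, cov_frame, spec)
            y = nodes[node].to_numpy()
            est = SurveyGLM(family=fam, single_psu=self.single_psu, alpha=self.alpha)
            est.fit(X, y, design, subpop=base_mask)
            if not est.converged_:
                raise NonConvergenceError(node)
            node_results[node] = est.result_
            n_by_node[node] = est.n_used_
            p = len(est.params_)
            slices[node] = slice(pos, pos + p)
            for j, t in enumerate(est.names_):
                term_index[(node, t)] = pos + j
            params_all.append(est.params_)
            score_blocks.append(est._scores_full_)
            B_blocks.append(est._B_)
            if fam == "linear":
                resid = y[est._dom_] - est._mu_
                sigma2[node] = float(np.average(resid**2, weights=est._w_))
            pos += p

        params = np.concatenate(params_all)
        scores = np.hstack(score_blocks)
        M = taylor_variance(scores, design, single_psu=self.single_psu)
        from scipy.linalg import block_diag

        B = block_diag(*B_blocks)
        Binv = np.linalg.inv(B)
        cov = Binv @ M @ Binv
        cov = (cov + cov.T) / 2.0
        return PathFit(
            node_results,
            params,
            cov,
            slices,
            term_index,
            sigma2,
            "factorized",
            self.n_missing_genotype_,
            n_by_node,
        )

    # --- Monte-Carlo EM for missing continuous mediators -----------------
    def _fit_fiml_mc(
        self,
        df: pd.DataFrame,
        nodes: pd.DataFrame,
        cov_frame: pd.DataFrame,
        design: SurveyDesign,
        base_mask: np.ndarray,
        spec: PathModelSpec,
    ) -> PathFit:
        start = self._fit_factorized(nodes, cov_frame, design, base_mask, spec)
        fam = spec.families
        linear_nodes = [n for n in spec.endogenous() if fam[n] == "linear"]
        children = {n: [t for s, t in spec.edges if s == n] for n in spec.node_names}

        node_arr = {n: nodes[n].to_numpy() for n in spec.node_names}
        # integrable records: exactly one missing linear mediator with all of
        # its parents observed and at least one observed child
        cand: dict[int, str] = {}
        for m in linear_nodes:
            parents_obs = np.ones(len(nodes), dtype=bool)
            for p in spec.parents(m):
                parents_obs &= ~np.isnan(node_arr[p])
            child_obs = np.zeros(len(nodes), dtype=bool)
            for c in children[m]:
                child_obs |= ~np.isnan(node_arr[c])
            rows = np.flatnonzero(
                base_mask & np.isnan(node_arr[m]) & parents_obs & child_obs
            )
            for r in rows:
                if r in cand:
                    cand.pop(r)  # >1 integrable mediator: fall back to available case
                else:
                    cand[r] = m
        if not cand:
            return dataclasses.replace(start, method="fiml_mc")

        rows = np.array(sorted(cand), dtype=int)
        med = np.array([cand[r] for r in rows])
        S = self.mc_draws
        z = np.random.default_rng(
            np.random.SeedSequence(self.mc_seed, spawn_key=(101,))
        ).standard_normal((len(rows), S))

        params = {n: start.node_results[n].params.copy() for n in spec.endogenous()}
        names = {n: list(start.node_results[n].names) for n in spec.endogenous()}
        sigma2 = dict(start.sigma2)

        def eq_X(node: str, nd: dict[str, np.ndarray], idx: np.ndarray) -> np.ndarray:
            cols = [np.ones(len(idx))]
            for p in spec.parents(node):
                cols.append(nd[p][idx])
            return np.hstack([np.column_stack(cols), cov_frame.to_numpy()[idx, 1:]])

        w_full = design.weights
        prev = np.concatenate([params[n] for n in spec.endogenous()])
        for _ in range(self.em_max_iter):
            # E-step: draw mediators from their current conditional, weight by
            # observed-children likelihood
            frac_rows: dict[str, list] = {n: [] for n in spec.endogenous()}
            imput = {}
            for m in sorted(set(med)):
                sel = rows[med == m]
                zsel = z[np.isin(rows, sel)]
                Xm = eq_X(m, node_arr, sel)
                mu = Xm @ params[m]
                sd = np.sqrt(sigma2[m])
                draws = mu[:, None] + sd * zsel  # (k, S)
                logw = np.zeros_like(draws)
                for c in children[m]:
                    yobs = node_arr[c][sel]
                    obs = ~np.isnan(yobs)
                    if not obs.any():
                        continue
                    # child design matrix with mediator column replaced by draws
                    pc = spec.parents(c)
                    base = eq_X(c, node_arr, sel)
                    j = 1 + pc.index(m)  # after intercept
                    for s_i in range(S):
                        base[:, j] = draws[:, s_i]
                        eta = base @ params[c]
                        if fam[c] == "logit":
                            pr = 1.0 / (1.0 + np.exp(-eta))
                            pr = np.clip(pr, 1e-12, 1 - 1e-12)
                            ll = yobs * np.log(pr) + (1 - yobs) * np.log1p(-pr)
                        else:
                            ll = -0.5 * (yobs - eta) ** 2 / sigma2[c]
                        ll = np.where(obs, ll, 0.0)
                        logw[:, s_i] += ll
                logw -= logw.max(axis=1, keepdims=True)
                wts = np.exp(logw)
                wts /= wts.sum(axis=1, keepdims=True)
                imput[m] = (sel, draws, wts)

            # M-step: refit every equation on original + fractional pseudo-data
            new_params = {}
            new_sigma2 = {}
            for node in spec.endogenous():
                y = node_arr[node]
                dom = base_mask & ~np.isnan(y)
                Xfull = eq_X(node, node_arr, np.arange(len(nodes)))
                dom &= ~np.isnan(Xfull).any(axis=1)
                Xs = [Xfull[dom]]
                ys = [y[dom]]
                ws = [w_full[dom]]
                for m, (sel, draws, wts) in imput.items():
                    pn = spec.parents(node)
                    if node == m:
                        # pseudo-observations of the mediator itself
                        ok = np.ones(len(sel), dtype=bool)
                        Xm = eq_X(node, node_arr, sel)
                        for s_i in range(S):
                            Xs.append(Xm[ok])
                            ys.append(draws[ok, s_i])
                            ws.append(w_full[sel][ok] * wts[ok, s_i])
                    elif m in pn:
                        yobs = y[sel]
                        ok = ~np.isnan(yobs) & base_mask[sel]
                        if not ok.any():
                            continue
                        Xm = eq_X(node, node_arr, sel)
                        j = 1 + pn.index(m)
                        other_ok = ~np.isnan(np.delete(Xm, j, axis=1)).any(axis=1)
                        ok &= other_ok
                        for s_i in range(S):
                            Xi = Xm[ok].copy()
                            Xi[:, j] = draws[ok, s_i]
                            Xs.append(Xi)
                            ys.append(yobs[ok])
                            ws.append(w_full[sel][ok] * wts[ok, s_i])
                Xa = np.vstack(Xs)
                ya = np.concatenate(ys)
                wa = np.concatenate(ws)
                famobj = sm.families.Binomial() if fam[node] == "logit" else sm.families.Gaussian()
                res = sm.GLM(ya, Xa, family=famobj, var_weights=wa).fit()
                new_params[node] = np.asarray(res.params)
                if fam[node] == "linear":
                    resid = ya - Xa @ new_params[node]
                    new_sigma2[node] = float(np.average(resid**2, weights=wa))
            params = new_params
            sigma2 = {**sigma2, **new_sigma2}
            cur = np.concatenate([params[n] for n in spec.endogenous()])
            if np.max(np.abs(cur - prev)) < self.em_tol * (1 + np.max(np.abs(prev))):
                break
            prev = cur

        # final inference pass: survey sandwich on the augmented data
        return self._augmented_sandwich(
            nodes, cov_frame, design, base_mask, spec, params, sigma2, imput, start
        )

    def _augmented_sandwich(
        self, nodes, cov_frame, design, base_mask, spec, params, sigma2, imput, start
    ) -> PathFit:
        """Design-based covariance at the EM solution, using fractionally
        weighted pseudo-records appended to the design (approximation
        documented in the methods note)."""
        S = self.mc_draws
        fam = spec.families
        node_arr = {n: nodes[n].to_numpy() for n in spec.node_names}
        # build augmented cohort rows
        aug_idx: list[np.ndarray] = []
        aug_vals: dict[str, list[np.ndarray]] = {n: [] for n in spec.node_names}
        aug_w: list[np.ndarray] = []
        for m, (sel, draws, wts) in imput.items():
            for s_i in range(S):
                aug_idx.append(sel)
                for n in spec.node_names:
                    v = node_arr[n][sel].copy()
                    if n == m:
                        v = draws[:, s_i]
                    aug_vals[n].append(v)
                aug_w.append(design.weights[sel] * wts[:, s_i])
        idx_all = np.concatenate([np.arange(len(nodes))] + aug_idx)
        nodes_aug = pd.DataFrame(
            {
                n: np.concatenate([node_arr[n]] + aug_vals[n])
                for n in spec.node_names
            }
        )
        cov_aug = pd.DataFrame(
            cov_frame.to_numpy()[idx_all], columns=cov_frame.columns
        )
        w_aug = np.concatenate([design.weights] + aug_w)
        design_aug = SurveyDesign(
            design.strata[idx_all], design.psu[idx_all], np.maximum(w_aug, 1e-300)
        )
        mask_aug = base_mask[idx_all]
        # zero out the original rows of integrated mediators (they are NaN
        # there anyway) — handled by complete-case logic in SurveyGLM
        fit = PathModel(
            spec=spec, method="factorized", single_psu=self.single_psu, alpha=self.alpha
        )
        fit.n_missing_genotype_ = self.n_missing_genotype_
        out = fit._fit_factorized(nodes_aug, cov_aug, design_aug, mask_aug, spec)
        return dataclasses.replace(
            out, method="fiml_mc", n_missing_genotype=self.n_missing_genotype_
        )


def fit_path_model(
    cohort: pd.DataFrame,
    spec: PathModelSpec | None,
    design: SurveyDesign,
    **kwargs,
) -> PathFit:
    """Convenience wrapper: fit the path model and return its :class:`PathFit`."""
    model = PathModel(spec=spec, **kwargs)
    model.fit(cohort, design)
    return model.result_


def _fit_of(model_or_fit) -> PathFit:
    if isinstance(model_or_fit, PathFit):
        return model_or_fit
    return model_or_fit.result_


def _spec_of(model_or_fit, spec: PathModelSpec | None) -> PathModelSpec:
    if spec is not None:
        return spec
    if isinstance(model_or_fit, PathModel):
        return model_or_fit.spec_
    raise ValueError("a PathModelSpec is required when passing a bare PathFit")


def effect_decomposition(
    model_or_fit,
    source: str,
    target: str,
    spec: PathModelSpec | None = None,
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Enumerate direct and indirect pathways and decompose the total effect.

    Indirect effect along a path = product of its edge coefficients on the
    linear-predictor scale; SEs by the multivariate delta method with the
    joint sandwich covariance; total = direct + sum of indirects (exactly,
    by construction). When the target is a logit node the exponentiated
    (odds-ratio) form is attached. No path between the nodes yields an empty
    list.
    """
    fit = _fit_of(model_or_fit)
    spec = _spec_of(model_or_fit, spec)
    g = spec.graph()
    if source not in g or target not in g:
        raise KeyError(f"unknown node in ({source}, {target})")
    order = {n: i for i, n in enumerate(spec.node_names)}
    if order[source] >= order[target]:
        raise ValueError("source must precede target in the temporal order")
    paths = sorted(nx.all_simple_paths(g, source, target), key=lambda p: (len(p), p))
    if not paths:
        return []
    z = stats.norm.ppf(1 - alpha / 2)
    p_total = len(fit.params)
    target_logit = spec.families[target] == "logit"

    def estimate_for(path: list[str]) -> tuple[float, np.ndarray]:
        edges = list(zip(path[:-1], path[1:]))
        coefs = np.array([fit.edge_coef(e)[0] for e in edges])
        grad = np.zeros(p_total)
        for j, (s, t) in enumerate(edges):
            others = np.prod(np.delete(coefs, j)) if len(coefs) > 1 else 1.0
            grad[fit.term_index[(t, s)]] += others
        return float(np.prod(coefs)), grad

    out: list[EffectEstimate] = []
    total_est = 0.0
    total_grad = np.zeros(p_total)
    for path in paths:
        est, grad = estimate_for(path)
        se = float(np.sqrt(grad @ fit.cov @ grad))
        kind = "direct" if len(path) == 2 else "indirect"
        ci = (est - z * se, est + z * se)
        expo = (np.exp(est), np.exp(ci[0]), np.exp(ci[1])) if target_logit else None
        out.append(EffectEstimate(source, target, kind, path, est, se, ci, expo))
        total_est += est
        total_grad += grad
    se_t = float(np.sqrt(total_grad @ fit.cov @ total_grad))
    ci_t = (total_est - z * se_t, total_est + z * se_t)
    expo_t = (np.exp(total_est), np.exp(ci_t[0]), np.exp(ci_t[1])) if target_logit else None
    out.append(
        EffectEstimate(source, target, "total", [source, target], total_est, se_t, ci_t, expo_t)
    )
    return out


def edge_odds_ratio(
    model_or_fit,
    edge: tuple[str, str],
    spec: PathModelSpec | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Exponentiated edge coefficient for a logit-node target.

    OR = exp(coef), CI = exp(coef +/- z SE). Linear targets raise: their
    coefficients are mean differences, not log odds.
    """
    fit = _fit_of(model_or_fit)
    spec = _spec_of(model_or_fit, spec)
    src, dst = edge
    if spec.families.get(dst) != "logit":
        raise ValueError(f"edge target {dst!r} is not a logit node; no odds ratio defined")
    est, se = fit.edge_coef(edge)
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (est - z * se, est + z * se)
    return EffectEstimate(
        src, dst, "direct", [src, dst], est, se, ci,
        (float(np.exp(est)), float(np.exp(ci[0])), float(np.exp(ci[1]))),
    )
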