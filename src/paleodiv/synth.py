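"""Synthetic fossil records with known truth.

Every estimator in this package corrects an observed record for
incomplete, uneven sampling; testing them requires records whose true
diversity history is known.  This module generates them:

* a discrete-bin birth--death process produces taxon durations with
  stated per-bin origination and extinction rates (a taxon alive in bin i
  suffers extinction before the next bin with probability
  ``1 - exp(-mu_i)``; new taxa arise as Poisson(lambda_i * N_i));
* a sampling layer turns durations into occurrence tables with per-bin
  Poisson sampling intensity, clustering of occurrences into collections
  and of collections into publications, and optional "age smearing" that
  widens occurrence age ranges across bin boundaries (exercising the
  unconstrained binning policy);
* a topology generator builds random binary trees consistent with
  origination order (no taxon branches from a later-originating one),
  optionally degraded with polytomies;
* a driver-response generator couples a diversity-like response to a
  covariate's AR(1) residuals with known effect size.

The default "J/K-like" scenario shapes the rates and sampling the way a
boundary extinction looks in the record: a richness ramp, one
high-extinction bin, suppressed origination afterwards, and a five-fold
sampling crash in the two post-event bins.  All outputs are
bit-reproducible from (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dendropy

from .bins import BinScheme, tenmyr_bins, stage_bins
from .drivers import EnvSeries, ar1_residuals
from .occdata import OccurrenceTable, TaxonRange, COLUMNS
from .series import DiversitySeries

__all__ = [
    "SimTruth",
    "simulate_ranges",
    "simulate_occurrences",
    "simulate_tree",
    "simulate_driver_response",
    "load_scenario",
    "simulate_scenario",
    "relative_l1",
]


@dataclass
class SimTruth:
    """Ground truth retained alongside every generated dataset."""

    scheme: BinScheme
    origination: dict[str, float]  # taxon -> true origination age (Ma)
    extinction: dict[str, float]   # taxon -> true extinction age (Ma)
    mu_star: np.ndarray            # per-bin true extinction rate
    lambda_star: np.ndarray        # per-bin true origination rate
    richness: np.ndarray           # per-bin true standing richness
    sampling: np.ndarray | None = None
    beta: float | None = None
    seed: int = 0

    @property
    def per_capita_origination(self) -> np.ndarray:
        """Per-capita origination rate implied by the birth step.

        The generator adds Poisson(lambda_i * N_i) taxa per bin, so the
        per-capita origination rate that boundary-crosser and three-timer
        estimators are defined to measure is ``ln(1 + lambda_i)`` (the log
        ratio of cohort size after to before the bin's originations), not
        lambda_i itself.  Extinction needs no such mapping: the survival
        probability is exp(-mu_i) by construction.
        """
        return np.log1p(self.lambda_star)

    def alive_in_bin(self, i: int) -> list[str]:
        b = self.scheme[i]
        return [
            t
            for t, orig in self.origination.items()
            if b.overlaps_range(orig, self.extinction[t])
        ]

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "origination": self.origination,
            "extinction": self.extinction,
            "mu_star": list(map(float, self.mu_star)),
            "lambda_star": list(map(float, self.lambda_star)),
            "richness": list(map(float, self.richness)),
            "sampling": None if self.sampling is None else list(map(float, self.sampling)),
            "beta": self.beta,
            "seed": self.seed,
        }


def _per_bin(value, scheme: BinScheme) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, float), (len(scheme),)).copy()
    if (arr < 0).any():
        raise ValueError("rates and intensities must be non-negative")
    return arr


def simulate_ranges(
    n0: int,
    scheme: BinScheme,
    mu,
    lam,
    seed: int = 0,
) -> tuple[list[TaxonRange], SimTruth]:
    """Discrete-bin birth--death taxon durations.

    ``n0`` taxa exist at the scheme's older bound.  In each bin i every
    living taxon (including ones originating within the bin) goes extinct
    before the next bin with probability ``1 - exp(-mu_i)``; new taxa
    arise as Poisson(lambda_i * N_i) with N_i the standing diversity
    entering the bin.  Origination and extinction times are uniform
    within their bins.  Taxa surviving the last bin are censored at the
    scheme's younger bound.  Total extinction is permitted: later bins
    may be empty.
    """
    mu = _per_bin(mu, scheme)
    lam = _per_bin(lam, scheme)
    rng = np.random.default_rng(seed)
    origination: dict[str, float] = {}
    extinction: dict[str, float] = {}
    counter = 0

    def new_taxon(orig_age: float) -> str:
        nonlocal counter
        name = f"t{counter:04d}"
        counter += 1
        origination[name] = float(orig_age)
        return name

    alive = [new_taxon(scheme.older_bound) for _ in range(n0)]
    for i, b in enumerate(scheme):
        n_entering = len(alive)
        n_new = rng.poisson(lam[i] * n_entering) if n_entering else 0
        newborn_ages = np.sort(
            b.older - rng.random(n_new) * b.duration
        )[::-1]
        newborns = [new_taxon(a) for a in newborn_ages]
        survivors = []
        p_ext = 1.0 - np.exp(-mu[i])
        for taxon in alive + newborns:
            if rng.random() < p_ext:
                lo = b.younger
                hi = min(b.older, origination[taxon])
                extinction[taxon] = float(hi - rng.random() * (hi - lo))
            else:
                survivors.append(taxon)
        alive = survivors
    for taxon in alive:
        extinction[taxon] = scheme.younger_bound

    richness = np.zeros(len(scheme))
    for i, b in enumerate(scheme):
        richness[i] = sum(
            1
            for t, orig in origination.items()
            if b.overlaps_range(orig, extinction[t])
        )
    truth = SimTruth(
        scheme=scheme,
        origination=origination,
        extinction=extinction,
        mu_star=mu,
        lambda_star=lam,
        richness=richness,
        seed=seed,
    )
    ranges = []
    for t in sorted(origination):
        fad, lad = origination[t], extinction[t]
        fad_bin = scheme.bin_for_age(fad) or scheme[0]
        lad_bin = scheme.bin_for_age(lad) or scheme[-1]
        ranges.append(TaxonRange(t, fad, lad, fad_bin.label, lad_bin.label))
    return ranges, truth


def simulate_occurrences(
    truth: SimTruth,
    r,
    collections_per_bin: int = 20,
    pubs_per_bin: int = 6,
    age_smear: float = 0.0,
    seed: int = 0,
    realm: str = "nonmarine",
    continent: str = "Other",
) -> OccurrenceTable:
    """Sample an occurrence table from true taxon durations.

    Each taxon alive in a bin yields Poisson(r_i) occurrences there, each
    assigned to one of the bin's collections uniformly at random;
    collections are spread over the bin's publications.  Occurrence ages
    are points drawn within the overlap of the taxon's duration and the
    bin.  With probability ``age_smear`` an occurrence's age range is
    instead widened to straddle the boundary with the adjacent younger
    bin, producing the temporally uncertain records the unconstrained
    binning policy is for.
    """
    scheme = truth.scheme
    r = _per_bin(r, scheme)
    if not 0.0 <= age_smear <= 1.0:
        raise ValueError("age_smear is a probability")
    rng = np.random.default_rng(seed)
    rows = []
    occ_id = 0
    for i, b in enumerate(scheme):
        colls = [f"c{i:02d}_{j:03d}" for j in range(collections_per_bin)]
        pubs = {
            c: f"p{i:02d}_{rng.integers(pubs_per_bin):03d}" for c in colls
        }
        for taxon in truth.alive_in_bin(i):
            n_occ = rng.poisson(r[i])
            orig = truth.origination[taxon]
            ext = truth.extinction[taxon]
            lo = max(b.younger, ext)
            hi = min(b.older, orig)
            for _ in range(n_occ):
                coll = colls[rng.integers(collections_per_bin)]
                age = hi - rng.random() * max(hi - lo, 0.0)
                if age <= b.younger:  # keep inside the half-open bin
                    age = np.nextafter(b.younger, b.older)
                age_max = age_min = age
                if age_smear > 0 and rng.random() < age_smear and i + 1 < len(scheme):
                    nxt = scheme[i + 1]
                    age_max = b.older
                    age_min = np.nextafter(nxt.younger, nxt.older)
                rows.append(
                    (
                        f"o{occ_id:06d}", taxon, taxon, "", coll, pubs[coll],
                        age_max, age_min, realm, continent,
                    )
                )
                occ_id += 1
    df = pd.DataFrame(rows, columns=COLUMNS)
    table = OccurrenceTable(df, meta={"seed": seed, "age_smear": age_smear})
    return table


def simulate_tree(
    truth: SimTruth,
    seed: int = 0,
    polytomy_fraction: float = 0.0,
) -> tuple[dendropy.Tree, dict[str, float], dict[str, float]]:
    """Random binary topology consistent with origination order.

    Taxa are attached in order of origination (oldest first), each as
    sister to a uniformly chosen existing tip — so no taxon ever branches
    from a later-originating lineage.  ``polytomy_fraction`` of the
    internal edges are then collapsed into polytomies.  Returns the tree
    with the true first (origination) and last (extinction) appearance
    maps.
    """
    taxa = sorted(
        truth.origination, key=lambda t: (-truth.origination[t], t)
    )
    if len(taxa) < 2:
        raise ValueError("tree simulation needs at least two taxa")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)

    def make_tip(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxon_ns.new_taxon(label)
        return node

    tips: list[dendropy.Node] = [make_tip(taxa[0]), make_tip(taxa[1])]
    tree.seed_node.add_child(tips[0])
    tree.seed_node.add_child(tips[1])
    for label in taxa[2:]:
        host = tips[rng.integers(len(tips))]
        parent = host.parent_node
        parent.remove_child(host)
        joint = dendropy.Node()
        joint.add_child(host)
        new_tip = make_tip(label)
        joint.add_child(new_tip)
        parent.add_child(joint)
        tips.append(new_tip)
    if polytomy_fraction > 0:
        internal = [
            n
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        for node in internal:
            if rng.random() < polytomy_fraction:
                parent = node.parent_node
                for c in list(node.child_nodes()):
                    node.remove_child(c)
                    parent.add_child(c)
                parent.remove_child(node)
    fads = {t: truth.origination[t] for t in taxa}
    lads = {t: truth.extinction[t] for t in taxa}
    return tree, fads, lads


def simulate_driver_response(
    driver: EnvSeries,
    beta: float,
    phi: float = 0.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> DiversitySeries:
    """Response series coupled to a driver's AR(1) residuals.

    ``y_t = beta * e_t + u_t`` where e_t are the driver's detrended
    residuals and u_t is an AR(1)(phi, sigma) noise process.  The result
    is a centred anomaly series (negative values allowed); its first bin
    is undefined when beta != 0 because the first residual is.
    """
    scheme = driver.scheme
    if scheme is None:
        raise ValueError("driver series must be aligned to a bin scheme")
    n = len(scheme)
    rng = np.random.default_rng(seed)
    u = np.zeros(n)
    if sigma > 0:
        u[0] = rng.normal(0.0, sigma)
        for t in range(1, n):
            u[t] = phi * u[t - 1] + rng.normal(0.0, sigma)
    if beta == 0.0:
        y = u
    else:
        e = ar1_residuals(driver).residuals
        y = beta * e + u
    return DiversitySeries(
        scheme,
        y,
        label="sim_response",
        meta={"beta": beta, "phi": phi, "sigma": sigma, "seed": seed},
        allow_negative=True,
    )


def relative_l1(values: np.ndarray, truth: np.ndarray) -> float:
    """Shape discrepancy between two positive trajectories.

    Both series are normalized by their mean over the bins where
    ``values`` is defined, removing scale (a subsampled richness is not
    on the same scale as true richness); the result is the mean absolute
    difference of the normalized series.
    """
    values = np.asarray(values, float)
    truth = np.asarray(truth, float)
    mask = np.isfinite(values) & np.isfinite(truth)
    if mask.sum() < 2:
        return float("nan")
    v = values[mask] / values[mask].mean()
    t = truth[mask] / truth[mask].mean()
    return float(np.mean(np.abs(v - t)))


_SCENARIO_FILE = "jk_scenario.yaml"


def load_scenario(path: str | Path | None = None) -> dict:
    """Load a scenario YAML; defaults to the shipped J/K-like scenario."""
    if path is None:
        text = (
            resources.files("paleodiv") / "data" / _SCENARIO_FILE
        ).read_text()
    else:
        text = Path(path).read_text()
    sc = yaml.safe_load(text)
    required = {"n0", "bins", "mu", "lambda", "sampling"}
    missing = required - set(sc)
    if missing:
        raise ValueError(f"scenario lacks keys: {sorted(missing)}")
    return sc


def scenario_scheme(sc: dict) -> BinScheme:
    if sc["bins"] == "tenmyr":
        return tenmyr_bins()
    if sc["bins"] == "stage":
        return stage_bins()
    raise ValueError(f"unknown scheme name {sc['bins']!r} in scenario")


@dataclass
class ScenarioRealization:
    """One seeded draw of a scenario: truth plus the observable record."""

    truth: SimTruth
    ranges: list[TaxonRange]
    occurrences: OccurrenceTable
    tree: dendropy.Tree
    fads: dict[str, float]
    lads: dict[str, float]
    driver: EnvSeries | None = None
    response: DiversitySeries | None = None
    meta: dict = field(default_factory=dict)


def simulate_scenario(sc: dict | None = None, seed: int = 0) -> ScenarioRealization:
    """Run a full scenario: durations, occurrences, tree and (optionally)
    a driver-coupled response, all from one seed."""
    sc = sc or load_scenario()
    scheme = scenario_scheme(sc)
    ranges, truth = simulate_ranges(
        int(sc["n0"]), scheme, sc["mu"], sc["lambda"], seed=seed
    )
    occ = simulate_occurrences(
        truth,
        sc["sampling"],
        collections_per_bin=int(sc.get("collections_per_bin", 20)),
        pubs_per_bin=int(sc.get("pubs_per_bin", 6)),
        age_smear=float(sc.get("age_smear", 0.0)),
        seed=seed + 1,
    )
    if len(truth.origination) >= 2:
        tree, fads, lads = simulate_tree(
            truth, seed=seed + 2,
            polytomy_fraction=float(sc.get("polytomy_fraction", 0.0)),
        )
    else:  # pragma: no cover - degenerate total-extinction draw
        tree, fads, lads = None, {}, {}
    driver = response = None
    if "driver" in sc:
        d = sc["driver"]
        rng = np.random.default_rng(seed + 3)
        # a smooth autocorrelated covariate standing in for e.g. sea level
        x = np.zeros(len(scheme))
        x[0] = rng.normal()
        for t in range(1, len(scheme)):
            x[t] = 0.7 * x[t - 1] + rng.normal()
        driver = EnvSeries(d.get("name", "driver"), x, scheme)
        response = simulate_driver_response(
            driver,
            beta=float(d.get("beta", 0.8)),
            phi=float(d.get("phi", 0.3)),
            sigma=float(d.get("sigma", 0.3)),
            seed=seed + 4,
        )
    return ScenarioRealization(
        truth=truth,
        ranges=ranges,
        occurrences=occ,
        tree=tree,
        fads=fads,
        lads=lads,
        driver=driver,
        response=response,
        meta={"scenario": sc.get("name", "unnamed"), "seed": seed},
    )
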