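"""Exact event-driven (Gillespie) individual-based simulation of the hierarchy.

Every cell is represented individually.  Waiting times are exponential with
total rate ``sum_i r_i * n_i``; the dividing compartment is drawn
proportionally to its aggregate rate and the cell uniformly within it —
distributionally identical to per-cell rates at O(#compartments) cost per
event.  A division resolves to

* ``differentiate`` (probability ``eps``): two daughters enter compartment
  ``i + 1``; from the last compartment the daughters leave the system,
* ``self-renew`` (``1 - eps - u``): one additional cell in compartment ``i``,
* ``mutate`` (``u``): the cell is replaced by a single cell carrying one more
  mutation in the same compartment — count-conserving, matching the
  deterministic mutation flux (the division-with-one-mutant-daughter variant
  is available behind ``mutation_division=True`` and deviates from the
  deterministic means).

The full clonal history is recorded: each mutation event founds a unique
clone (infinite-sites), and the forest of clones can be exported as newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import HierarchyParams, validate_params

__all__ = [
    "CloneRecord",
    "EventLog",
    "GillespieResult",
    "EnsembleSummary",
    "gillespie_run",
    "replicate_ensemble",
    "clone_census",
    "export_lineage_newick",
    "FOUNDER_CLONE",
]

#: clone id of the unmutated founder lineage.
FOUNDER_CLONE = 0

_OUTCOMES = ("differentiate", "self-renew", "mutate")


@dataclass(frozen=True)
class CloneRecord:
    """One mutation event: a unique clone in the infinite-sites sense."""

    clone_id: int
    parent_id: int
    birth_time: float
    origin_compartment: int
    k: int


@dataclass
class EventLog:
    """Columnar record of division events (strictly increasing times)."""

    times: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    outcomes: list = field(default_factory=list)
    compartments: list = field(default_factory=list)
    ks: list = field(default_factory=list)
    clone_ids: list = field(default_factory=list)
    daughters: list = field(default_factory=list)

    def append(self, t, cell, outcome, comp, k, clone, daughters):
        self.times.append(t)
        self.cell_ids.append(cell)
        self.outcomes.append(outcome)
        self.compartments.append(comp)
        self.ks.append(k)
        self.clone_ids.append(clone)
        self.daughters.append(tuple(daughters))

    def __len__(self):
        return len(self.times)


@dataclass
class GillespieResult:
    events: EventLog
    clones: list
    snapshot_times: np.ndarray
    snapshots: np.ndarray  # (n_compartments, k_max + 1, n_snapshots)
    clone_reach: dict  # clone id -> furthest compartment its cells entered
    final_time: float
    final_population: int
    truncated: bool
    truncation_leakage: int  # mutation events beyond k_max
    seed: object
    params: HierarchyParams = field(repr=False, default=None)


def gillespie_run(
    params: HierarchyParams,
    t_end: float,
    seed,
    max_cells: int = 1_000_000,
    snapshot_times=None,
    record_events: bool = True,
    mutation_division: bool = False,
) -> GillespieResult:
    """Simulate one realization until ``t_end``, extinction, or the cap.

    Identical ``seed`` yields an identical event log.  Runs that hit
    ``max_cells`` are flagged ``truncated`` (accumulation-regime inputs
    require an explicit cap for this reason).
    """
    params = validate_params(params)
    if max_cells <= params.n0:
        raise ValueError("max_cells must exceed the founder cell count")
    rng = np.random.default_rng(seed)
    n = params.n_compartments
    km = params.k_max
    eps = params.eps_table
    u = params.u
    rates = params.rate_schedule().rates

    # cell store (index = cell id)
    comp = []  # compartment (1-based), 0 = departed/dead
    kcnt = []
    clone = []
    by_comp = [[] for _ in range(n + 1)]  # per-compartment alive cell ids

    def add_cell(ci, k, g):
        cid = len(comp)
        comp.append(ci)
        kcnt.append(k)
        clone.append(g)
        by_comp[ci].append(cid)
        if ci > clone_reach.get(g, 0):
            clone_reach[g] = ci
        return cid

    def remove_cell(cid):
        ci = comp[cid]
        lst = by_comp[ci]
        # swap-remove by value; lists stay small in the wave regime
        j = lst.index(cid)
        lst[j] = lst[-1]
        lst.pop()
        comp[cid] = 0

    clone_reach: dict[int, int] = {}
    f = params.founder_compartment
    for _ in range(int(params.n0)):
        add_cell(f, 0, FOUNDER_CLONE)

    clones: list[CloneRecord] = []
    events = EventLog()
    next_clone = 1
    leakage = 0

    snaps = np.asarray(
        sorted(snapshot_times) if snapshot_times is not None else [], dtype=float
    )
    snap_counts = np.zeros((n, km + 1, snaps.size))
    snap_ptr = 0

    def record_snapshots_up_to(t_new):
        nonlocal snap_ptr
        while snap_ptr < snaps.size and snaps[snap_ptr] < t_new:
            for ci in range(1, n + 1):
                for cid in by_comp[ci]:
                    snap_counts[ci - 1, min(kcnt[cid], km), snap_ptr] += 1
            snap_ptr += 1

    t = 0.0
    truncated = False
    while True:
        counts = np.array([len(by_comp[ci]) for ci in range(1, n + 1)], dtype=float)
        pop = int(counts.sum())
        if pop == 0:
            break
        if pop >= max_cells:
            truncated = True
            break
        comp_rates = counts * rates
        total = comp_rates.sum()
        t_next = t + rng.exponential(1.0 / total)
        if t_next > t_end:
            record_snapshots_up_to(t_end + 0.0)
            t = t_end
            break
        record_snapshots_up_to(t_next)
        t = t_next
        ci = int(rng.choice(n, p=comp_rates / total)) + 1
        lst = by_comp[ci]
        cid = lst[int(rng.integers(len(lst)))]
        k = kcnt[cid]
        g = clone[cid]
        e = eps[ci - 1, min(k, km)]
        x = rng.random()
        if x < e:
            outcome = "differentiate"
            remove_cell(cid)
            ds = []
            if ci < n:
                ds = [add_cell(ci + 1, k, g), add_cell(ci + 1, k, g)]
        elif x < e + (1.0 - e - u):
            outcome = "self-renew"
            ds = [cid, add_cell(ci, k, g)]
        else:
            outcome = "mutate"
            gk = k + 1
            if gk > km:
                leakage += 1
            rec = CloneRecord(
                clone_id=next_clone,
                parent_id=g,
                birth_time=t,
                origin_compartment=ci,
                k=gk,
            )
            clones.append(rec)
            if mutation_division:
                # division variant: one unmutated and one mutated daughter
                remove_cell(cid)
                ds = [add_cell(ci, k, g), add_cell(ci, gk, next_clone)]
            else:
                # count-conserving replacement (matches the deterministic flux)
                kcnt[cid] = gk
                clone[cid] = next_clone
                clone_reach[next_clone] = max(clone_reach.get(next_clone, 0), ci)
                ds = [cid]
            next_clone += 1
        if record_events:
            events.append(t, cid, outcome, ci, k, g, ds)

    record_snapshots_up_to(np.inf)
    pop = sum(len(by_comp[ci]) for ci in range(1, n + 1))
    return GillespieResult(
        events=events,
        clones=clones,
        snapshot_times=snaps,
        snapshots=snap_counts,
        clone_reach=clone_reach,
        final_time=t,
        final_population=pop,
        truncated=truncated,
        truncation_leakage=leakage,
        seed=seed,
        params=params,
    )


@dataclass
class EnsembleSummary:
    """Per-(compartment, k, time) mean, SD and SE over independent replicates."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    n_runs: int
    n_excluded: int  # truncated runs excluded from the statistics


def replicate_ensemble(
    params: HierarchyParams,
    n_runs: int,
    t_grid,
    seed,
    max_cells: int = 1_000_000,
    include_truncated: bool = False,
) -> tuple[EnsembleSummary, list[GillespieResult]]:
    """Independent replicates via spawned seed streams.

    Returns the summary (dimensions matching a trajectory grid) and the
    per-replicate results.  Truncated runs are excluded from the statistics
    by default.
    """
    if n_runs < 2:
        raise ValueError("need at least two replicates")
    params = validate_params(params)
    t_grid = np.asarray(t_grid, dtype=float)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    results = []
    stacks = []
    n_excluded = 0
    for child in children:
        res = gillespie_run(
            params,
            t_end=float(t_grid[-1]) * 1.0000001,
            seed=child,
            max_cells=max_cells,
            snapshot_times=t_grid,
            record_events=False,
        )
        results.append(res)
        if res.truncated and not include_truncated:
            n_excluded += 1
            continue
        stacks.append(res.snapshots)
    arr = np.stack(stacks, axis=0)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    se = sd / np.sqrt(arr.shape[0])
    return (
        EnsembleSummary(
            times=t_grid,
            mean=mean,
            sd=sd,
            se=se,
            n_runs=arr.shape[0],
            n_excluded=n_excluded,
        ),
        results,
    )


def clone_census(result: GillespieResult, compartment: int) -> dict[int, int]:
    """Distinct clones whose progeny ever entered ``compartment``, by ``k``.

    Cells move strictly downstream, so a clone entered the compartment iff
    its furthest reach is at least ``compartment``.  Clone ids are unique per
    mutation event (infinite sites); the founder clone (k = 0) is not
    counted.
    """
    census: dict[int, int] = {}
    for rec in result.clones:
        if result.clone_reach.get(rec.clone_id, 0) >= compartment:
            census[rec.k] = census.get(rec.k, 0) + 1
    return census


# ----------------------------------------------------------------------
# lineage export
# ----------------------------------------------------------------------
def export_lineage_newick(clones, founder_label: str = "founder") -> str:
    """Newick string of the clone forest rooted at the founder clone.

    Node labels are ``c<id>.i<origin compartment>`` (dots, since newick
    readers commonly translate underscores to spaces) with branch lengths
    equal to the waiting time between the parent's and the clone's founding
    mutation.  Raises on cyclic parent links.
    """
    children: dict[int, list[CloneRecord]] = {}
    by_id = {FOUNDER_CLONE: None}
    for rec in clones:
        by_id[rec.clone_id] = rec
        children.setdefault(rec.parent_id, []).append(rec)
    for rec in clones:
        if rec.parent_id not in by_id:
            raise ValueError(
                f"clone {rec.clone_id} references unknown parent {rec.parent_id}"
            )
    # every clone must be reachable from the founder; a shortfall means the
    # parent links contain a cycle
    reachable = {FOUNDER_CLONE}
    stack = [FOUNDER_CLONE]
    while stack:
        cur = stack.pop()
        for rec in children.get(cur, []):
            reachable.add(rec.clone_id)
            stack.append(rec.clone_id)
    if len(reachable) != len(clones) + 1:
        raise ValueError("cyclic parent links in clone table")

    def birth(cid: int) -> float:
        rec = by_id[cid]
        return 0.0 if rec is None else rec.birth_time

    def render(cid: int, label: str, visiting: set) -> str:
        if cid in visiting:
            raise ValueError("cyclic parent links in clone table")
        visiting = visiting | {cid}
        kids = sorted(children.get(cid, []), key=lambda r: r.clone_id)
        sub = ",".join(
            render(
                r.clone_id,
                f"c{r.clone_id}.i{r.origin_compartment}",
                visiting,
            )
            + f":{r.birth_time - birth(cid):.12g}"
            for r in kids
        )
        return (f"({sub}){label}" if kids else label)

    return render(FOUNDER_CLONE, founder_label, set()) + ";"
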