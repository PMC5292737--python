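"""Forward simulation of element evolution along a dated host tree.

Each host branch carries resident element lineages that evolve neutrally
by a continuous-time substitution process (Jukes–Cantor or Kimura
two-parameter), exact per site: the number of substitution events on a
branch of duration ``t`` is Poisson with mean ``rate * t`` per site (the
jump chain of the exponential-waiting-time process), each event
replacing the base according to the model.  A horizontal-transfer event
copies the donor lineage's sequence onto the recipient branch at the
event time, either alongside the resident or replacing it (replacement
is the fate the invasion scenario predicts for resident lineages).
Within-branch duplications create additional resident copies, and
paralog specs graft an anciently diverged lineage (splitting from the
root lineage before the host root) into one taxon.

Everything is reproducible from the integer seed.  The truth object
records the element genealogy (Newick), per-branch substitution event
counts and realized parent/child differences, the event log, and the
set of element pairs whose genealogical divergence is younger than
their hosts' split — the pairs a detector should flag.

Degradation of single sequences (frameshifts, premature stops, large
deletions, tandem duplications) lives in :func:`degrade_element`; the
nine-element :func:`paper_like_fixture` wires both together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hosts import DatedHostTree

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HTEventSpec:
    """A configured transfer: donor -> recipient at ``time`` Myr ago.

    ``donor``/``recipient`` name a host taxon (the branch above that
    leaf) or a clade as a tuple of taxa (the stem branch above their
    MRCA).  ``donor_element`` picks a specific lineage label when the
    donor branch carries several.  ``direction_constraint`` is metadata
    recording which reproductive route the event presumes
    (``paternal_to_maternal``: the ordinary hemiclonal route;
    ``maternal_to_paternal``: requires maternal-haploset exclusion or
    androgenesis); it does not alter the simulation.
    """

    time: float
    donor: str | tuple
    recipient: str | tuple
    replace_resident: bool = True
    donor_element: str | None = None
    name: str | None = None
    direction_constraint: str | None = None


@dataclass
class DuplicationSpec:
    """A within-branch copy: a new resident lineage on the same branch."""

    time: float
    taxon: str | tuple
    source_element: str | None = None
    name: str | None = None


@dataclass
class ParalogSpec:
    """An anciently diverged lineage retained in one taxon only."""

    divergence_myr: float
    taxon: str
    name: str | None = None


@dataclass
class DegradationParams:
    """Degradation op counts/sizes applied to one sequence."""

    n_frameshifts: int = 0
    n_stops: int = 0
    deletion_lengths: tuple[int, ...] = ()
    duplication_lengths: tuple[int, ...] = ()


@dataclass
class SimulationConfig:
    host: DatedHostTree
    rate: float = 0.005          # substitutions/site/Myr
    seq_length: int = 3000
    model: str = "JC"            # or "K2P"
    kappa: float = 2.0
    ht_events: list[HTEventSpec] = field(default_factory=list)
    duplications: list[DuplicationSpec] = field(default_factory=list)
    paralogs: list[ParalogSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.seq_length < 300:
            raise ValueError("seq_length must be >= 300")
        if self.model not in ("JC", "K2P"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class SimulationTruth:
    element_tree_newick: str
    branch_substitutions: dict[str, int]   # node id -> Poisson events
    branch_diffs: dict[str, int]           # realized parent/child diffs
    event_log: list[dict]
    ht_pairs: list[tuple[str, str]]        # cross-taxon pairs younger
    #                                        than their host split
    pair_mrca_age: dict[str, float] = field(default_factory=dict)
    node_sequences: dict[str, str] | None = None

    def to_json(self) -> str:
        d = asdict(self)
        d["ht_pairs"] = [list(p) for p in self.ht_pairs]
        d.pop("node_sequences")
        return json.dumps(d, indent=1)


def jc_expected_p(rate: float, time_total: float) -> float:
    """JC closed form: expected p-distance after ``time_total`` Myr of
    total branch length (both lineages summed) at ``rate``."""
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * time_total))


# ---------------------------------------------------------------------------
# genealogy + sequences


def _host_branches(host: DatedHostTree):
    """clade frozenset -> (age_young, age_old) per host branch."""
    out = {}
    for node in host.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        young = host.root_age - node.distance_from_root()
        old = young + (node.edge.length or 0.0)
        out[leaves] = (young, old)
    return out


def _branch_key(spec) -> frozenset:
    return frozenset({spec}) if isinstance(spec, str) else frozenset(spec)


def simulate(config: SimulationConfig):
    """Run the simulation.

    Returns ``(records, mapping, truth)``: aligned rows keyed by element
    name (all the same length — no indels are simulated here), a mapping
    DataFrame (element_id, taxon, degenerate, fragment, coverage) and a
    :class:`SimulationTruth`.
    """
    host = config.host
    rng = np.random.default_rng(config.seed)
    branches = _host_branches(host)
    root_age = host.root_age

    nodes: dict[str, dict] = {}
    children: dict[str, list[str]] = {}
    counter = [0]

    def new_node(parent_id, age, kind, name=None):
        nid = name if name is not None else f"n{counter[0]}"
        counter[0] += 1
        if nid in nodes:
            raise ValueError(f"duplicate node name {nid!r}")
        nodes[nid] = {"id": nid, "parent": parent_id, "age": age,
                      "kind": kind}
        if parent_id is not None:
            children.setdefault(parent_id, []).append(nid)
        return nid

    # --- per-branch event timelines ------------------------------------
    events_by_branch: dict[frozenset, list] = {b: [] for b in branches}
    log = []
    for k, ev in enumerate(config.ht_events):
        dkey, rkey = _branch_key(ev.donor), _branch_key(ev.recipient)
        for key, role in ((dkey, "donor"), (rkey, "recipient")):
            if key not in branches:
                raise ValueError(f"no host branch for {sorted(key)}")
            young, old = branches[key]
            if not (young <= ev.time <= old):
                raise ValueError(
                    f"event time {ev.time} outside {role} branch "
                    f"interval [{young}, {old}] of {sorted(key)}"
                )
        name = ev.name or f"HT{k + 1}"
        events_by_branch[dkey].append((ev.time, "ht_out", name, ev))
        events_by_branch[rkey].append((ev.time, "ht_in", name, ev))
        log.append({
            "event": name, "time": ev.time, "donor": sorted(dkey),
            "recipient": sorted(rkey),
            "replace_resident": ev.replace_resident,
            "direction_constraint": ev.direction_constraint,
        })
    for k, dup in enumerate(config.duplications):
        key = _branch_key(dup.taxon)
        if key not in branches:
            raise ValueError(f"no host branch for {sorted(key)}")
        young, old = branches[key]
        if not (young <= dup.time <= old):
            raise ValueError(
                f"duplication time {dup.time} outside branch interval"
            )
        events_by_branch[key].append(
            (dup.time, "dup", dup.name or f"dup{k + 1}", dup))

    # --- walk the host tree, oldest events first ------------------------
    # live lineage: (genealogy node id of last split, label)
    pending_in: dict[str, str] = {}   # HT name -> recipient-side node

    def process_branch(branch_key, incoming, host_node):
        evs = sorted(events_by_branch[branch_key],
                     key=lambda e: (-e[0], e[1]))
        live = list(incoming)
        for t, action, name, spec in evs:
            if action == "ht_out":
                sel = 0
                if spec.donor_element is not None:
                    for idx, (_, lab) in enumerate(live):
                        if lab == spec.donor_element:
                            sel = idx
                            break
                nid, lab = live[sel]
                split = new_node(nid, t, "split")
                live[sel] = (split, lab)
                # recipient copy hangs off the same split node
                pending_in[name] = split
            elif action == "ht_in":
                if spec.replace_resident:
                    live = []
                # parent patched after the walk if the donor branch has
                # not been processed yet
                xfer = new_node(None, t, f"transfer:{name}")
                live.append((xfer, name))
            elif action == "dup":
                sel = 0
                if spec.source_element is not None:
                    for idx, (_, lab) in enumerate(live):
                        if lab == spec.source_element:
                            sel = idx
                            break
                nid, lab = live[sel]
                split = new_node(nid, t, "split")
                live[sel] = (split, lab)
                copy = new_node(split, t, f"dup:{name}")
                live.append((copy, name))
        if host_node.is_leaf():
            taxon = host_node.taxon.label
            return [
                (new_node(nid, 0.0, "tip"), taxon, lab)
                for nid, lab in live
            ]
        # host split: one shared split node per lineage, inherited by
        # every child branch, so sister copies coalesce at the split age
        split_age = branches[branch_key][0]
        shared = [(new_node(nid, split_age, "split"), lab)
                  for nid, lab in live]
        tips = []
        for child in host_node.child_nodes():
            ckey = frozenset(lf.taxon.label for lf in child.leaf_iter())
            tips.extend(process_branch(ckey, list(shared), child))
        return tips

    # pre-root stem for paralogs
    paralogs = sorted(config.paralogs, key=lambda p: -p.divergence_myr)
    for p in paralogs:
        if p.divergence_myr < root_age:
            raise ValueError("paralog divergence must pre-date the root")
    top_age = paralogs[0].divergence_myr if paralogs else root_age
    genealogy_root = new_node(None, top_age, "root", name="ROOT")
    paralog_tips = []
    cur = genealogy_root
    for i, p in enumerate(paralogs):
        if p.divergence_myr < nodes[cur]["age"]:
            cur = new_node(cur, p.divergence_myr, "split")
        tip = new_node(cur, 0.0, "tip")
        paralog_tips.append((tip, p.taxon, p.name or f"paralog{i + 1}",
                             True))
    host_root_node = cur if nodes[cur]["age"] == root_age else (
        new_node(cur, root_age, "split") if paralogs else genealogy_root
    )

    tips = []
    for child in host.tree.seed_node.child_nodes():
        ckey = frozenset(lf.taxon.label for lf in child.leaf_iter())
        tips.extend(process_branch(ckey, [(host_root_node, None)],
                                   child))

    # patch deferred transfer parents
    for name, donor_split in pending_in.items():
        for nid, nd in nodes.items():
            if nd["kind"] == f"transfer:{name}" and nd["parent"] is None:
                nd["parent"] = donor_split
                children.setdefault(donor_split, []).append(nid)
    orphan = [n for n, nd in nodes.items()
              if nd["parent"] is None and n != "ROOT"]
    if orphan:
        raise RuntimeError(f"unresolved transfer nodes: {orphan}")

    # --- tip naming ------------------------------------------------------
    name_of: dict[str, str] = {}
    per_taxon: dict[str, int] = {}
    for tip, taxon, lab in tips:
        per_taxon[taxon] = per_taxon.get(taxon, 0) + 1
        name_of[tip] = f"{taxon}_{per_taxon[taxon]}"
    for tip, taxon, nm, _ in paralog_tips:
        name_of[tip] = nm
    all_tips = [(t, tx, lab) for t, tx, lab in tips] + [
        (t, tx, None) for t, tx, nm, _ in paralog_tips
    ]

    # --- sequences -------------------------------------------------------
    L = config.seq_length
    seqs = {"ROOT": rng.integers(0, 4, size=L, dtype=np.int8)}
    subs: dict[str, int] = {}
    diffs: dict[str, int] = {}

    def evolve(parent_seq, t):
        seq = parent_seq.copy()
        if t <= 0:
            return seq, 0
        k = rng.poisson(config.rate * t, size=L)
        kmax = int(k.max())
        for rep in range(1, kmax + 1):
            sites = np.where(k >= rep)[0]
            if config.model == "JC":
                shift = rng.integers(1, 4, size=sites.size,
                                     dtype=np.int8)
                seq[sites] = (seq[sites] + shift) % 4
            else:
                p_ts = config.kappa / (config.kappa + 2.0)
                is_ts = rng.random(sites.size) < p_ts
                cur = seq[sites]
                ts_to = cur ^ 2                       # A<->G, C<->T
                tv_shift = np.where(rng.random(sites.size) < 0.5, 1, 3)
                tv_to = (cur + tv_shift.astype(np.int8)) % 4
                seq[sites] = np.where(is_ts, ts_to, tv_to)
        return seq, int(k.sum())

    done = {"ROOT"}
    pending = [n for n in nodes if n != "ROOT"]
    while pending:
        progressed = False
        for nid in list(pending):
            pid = nodes[nid]["parent"]
            if pid in done:
                t = nodes[pid]["age"] - nodes[nid]["age"]
                seqs[nid], n_ev = evolve(seqs[pid], t)
                subs[nid] = n_ev
                diffs[nid] = int((seqs[nid] != seqs[pid]).sum())
                done.add(nid)
                pending.remove(nid)
                progressed = True
        if not progressed:
            raise RuntimeError("genealogy has a dependency cycle")

    # --- outputs ---------------------------------------------------------
    records = {}
    mapping_rows = []
    taxon_of = {}
    for tip, taxon, _ in all_tips:
        elem = name_of[tip]
        records[elem] = _decode(seqs[tip])
        taxon_of[elem] = taxon
        mapping_rows.append({
            "element_id": elem, "taxon": taxon, "degenerate": 0,
            "fragment": 0, "aligned_start": 1, "aligned_end": L,
        })
    mapping = pd.DataFrame(mapping_rows)

    mrca_ages = _pairwise_mrca_ages(nodes, [t for t, _, _ in all_tips])
    ht_pairs = []
    pair_age = {}
    for (ta, tb), age in mrca_ages.items():
        a, b = name_of[ta], name_of[tb]
        key = "|".join(sorted((a, b)))
        pair_age[key] = age
        if taxon_of[a] != taxon_of[b]:
            host_age = host.split_age(taxon_of[a], taxon_of[b])
            if age < host_age - 1e-9:
                ht_pairs.append(tuple(sorted((a, b))))

    truth = SimulationTruth(
        element_tree_newick=_genealogy_newick(nodes, children, name_of),
        branch_substitutions=subs,
        branch_diffs=diffs,
        event_log=log,
        ht_pairs=sorted(ht_pairs),
        pair_mrca_age=pair_age,
        node_sequences={n: _decode(s) for n, s in seqs.items()},
    )
    return records, mapping, truth


def _pairwise_mrca_ages(nodes, tips):
    anc: dict[str, list[str]] = {}
    for t in tips:
        chain = []
        nid = t
        while nid is not None:
            chain.append(nid)
            nid = nodes[nid]["parent"]
        anc[t] = chain
    out = {}
    for i, a in enumerate(tips):
        seen = set(anc[a])
        for b in tips[i + 1:]:
            for nid in anc[b]:
                if nid in seen:
                    out[(a, b)] = nodes[nid]["age"]
                    break
    return out


def _decode(arr) -> str:
    return BASES[np.asarray(arr, dtype=np.int8)].tobytes().decode()


def _genealogy_newick(nodes, children, name_of) -> str:
    def blen(nid):
        pid = nodes[nid]["parent"]
        return 0.0 if pid is None else \
            nodes[pid]["age"] - nodes[nid]["age"]

    def rec(nid):
        kids = children.get(nid, [])
        if not kids:
            return f"{name_of.get(nid, nid)}:{blen(nid):g}"
        if len(kids) == 1:
            # absorb unifurcation
            sub = rec(kids[0])
            nm, _, bl = sub.rpartition(":")
            return f"{nm}:{float(bl) + blen(nid):g}"
        inner = ",".join(rec(k) for k in kids)
        return f"({inner}):{blen(nid):g}"

    return rec("ROOT") + ";"


# ---------------------------------------------------------------------------
# standalone degradation


def degrade_element(
    seq: str,
    params: DegradationParams,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Apply degradation ops to one ungapped sequence.

    Ops are drawn at uniform positions: large deletions remove their
    range, duplications tandem-repeat a block, frameshifts insert or
    delete one base, premature stops overwrite an in-frame codon (frame
    of position 1) with TAA.  Returns the degraded sequence and a log
    with 1-based coordinates on the *input* sequence.
    """
    if "-" in seq:
        raise ValueError("degrade_element expects ungapped input")
    rng = np.random.default_rng(seed)
    n = len(seq)
    ops = []
    for dl in params.deletion_lengths:
        if dl >= n:
            raise ValueError("deletion longer than sequence")
        start = int(rng.integers(1, n - dl + 1))
        ops.append(("deletion", start, start + dl - 1))
    for dl in params.duplication_lengths:
        if dl >= n:
            raise ValueError("duplication unit longer than sequence")
        start = int(rng.integers(1, n - dl + 1))
        ops.append(("duplication", start, start + dl - 1))
    for _ in range(params.n_frameshifts):
        pos = int(rng.integers(2, n))
        kind = "frameshift_del" if rng.random() < 0.5 \
            else "frameshift_ins"
        ops.append((kind, pos, pos))
    for _ in range(params.n_stops):
        cod = int(rng.integers(1, n // 3 - 1))
        ops.append(("stop", 3 * cod + 1, 3 * cod + 3))
    out = seq
    for kind, a, b in sorted(ops, key=lambda o: -o[1]):
        if kind in ("deletion", "frameshift_del"):
            out = out[:a - 1] + out[b:]
        elif kind == "duplication":
            out = out[:b] + out[a - 1:b] + out[b:]
        elif kind == "frameshift_ins":
            base = "ACGT"[int(rng.integers(0, 4))]
            out = out[:a] + base + out[a:]
        elif kind == "stop":
            out = out[:a - 1] + "TAA" + out[b:]
    log = [
        {"op": kind, "ref_start": a, "ref_end": b,
         "length": 1 if kind.startswith("frameshift") else b - a + 1}
        for kind, a, b in sorted(ops, key=lambda o: o[1])
    ]
    return out, log


# ---------------------------------------------------------------------------
# the nine-element fixture


def paper_like_fixture(seed: int = 0, seq_length: int = 3000,
                       rate: float = 0.005):
    """Synthetic nine-element dataset emulating the published structure.

    Five host taxa; two transfers (an old one from the *B. rossius*
    lineage into the *benazzii*/*maretimi* stem, replacing the resident,
    and a recent back-transfer of the deletion-carrying *maretimi* copy
    into *B. rossius*); an anciently diverged paralog in
    *grandii_grandii* (cross-taxon divergence above 0.5); a degenerate
    copy and a 5'-only fragment in *rossius*; a 426-bp deletion shared
    by the back-transferred pair.  Returns
    ``(records, mapping, truth, indel_profiles)``.
    """
    from .elements import StructuralVariant
    from .hosts import load_fixture_host_tree

    host = load_fixture_host_tree()
    cfg = SimulationConfig(
        host=host,
        rate=rate,
        seq_length=seq_length,
        model="JC",
        ht_events=[
            HTEventSpec(time=8.6, donor="rossius",
                        recipient=("benazzii", "maretimi"),
                        replace_resident=True, name="HT1",
                        direction_constraint="maternal_to_paternal"),
            HTEventSpec(time=0.8, donor="maretimi",
                        recipient="rossius", replace_resident=False,
                        donor_element="mardup", name="HT2",
                        direction_constraint="paternal_to_maternal"),
        ],
        duplications=[
            DuplicationSpec(time=6.0, taxon="rossius", name="rossdeg"),
            DuplicationSpec(time=1.0, taxon="maretimi", name="mardup"),
        ],
        paralogs=[
            ParalogSpec(divergence_myr=120.0, taxon="grandii_grandii",
                        name="R2BggB"),
        ],
        seed=seed,
    )
    records, mapping, truth = simulate(cfg)

    renames = {"atticus_1": "R2Ba", "grandii_grandii_1": "R2BggA",
               "benazzii_1": "R2Bgb", "maretimi_1": "R2Bgm",
               "maretimi_2": "R2Bgmdel", "rossius_1": "R2Brfun",
               "rossius_2": "R2Brdeg", "rossius_3": "R2Brdel"}
    records = {renames.get(k, k): v for k, v in records.items()}
    mapping["element_id"] = mapping["element_id"].map(
        lambda e: renames.get(e, e))
    truth.ht_pairs = sorted(
        tuple(sorted((renames.get(a, a), renames.get(b, b))))
        for a, b in truth.ht_pairs
    )
    truth.pair_mrca_age = {
        "|".join(sorted(renames.get(x, x)
                        for x in k.split("|"))): v
        for k, v in truth.pair_mrca_age.items()
    }
    for old, new in renames.items():
        truth.element_tree_newick = \
            truth.element_tree_newick.replace(old + ":", new + ":")

    # shared 426-bp deletion (inherited through the back-transfer):
    # identical coordinates -> identical gap columns
    for elem in ("R2Bgmdel", "R2Brdel"):
        row = records[elem]
        records[elem] = row[:1034] + "-" * 426 + row[1460:]
    # degenerate copy: premature stops scattered in frame
    deg = list(records["R2Brdeg"])
    rng = np.random.default_rng(seed + 1)
    for _ in range(4):
        cod = int(rng.integers(10, seq_length // 3 - 10))
        deg[3 * cod:3 * cod + 3] = "TAA"
    records["R2Brdeg"] = "".join(deg)
    mapping.loc[mapping.element_id == "R2Brdeg", "degenerate"] = 1
    # fragment: the back-transferred copy is known from its 5' half only
    half = seq_length // 2
    records["R2Brdel"] = records["R2Brdel"][:half] + \
        "-" * (seq_length - half)
    mapping.loc[
        mapping.element_id == "R2Brdel",
        ["fragment", "aligned_start", "aligned_end"],
    ] = [1, 1, half]

    indel_profiles = {
        "R2Bgmdel": {StructuralVariant("deletion", 1035, 1460, 426)},
        "R2Brdel": {StructuralVariant("deletion", 1035, 1460, 426)},
    }
    return records, mapping, truth, indel_profiles
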