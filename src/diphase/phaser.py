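"""Hi-C contact counting and stochastic phase assignment.

Each heterozygous block is a unit with two sequences: the alternate span
(haplotig ``a``, the hap1 minced sequence) and the primary span (``a'``,
hap2). Between two units a, b four contact counts exist -- w_ab, w_ab',
w_a'b, w_a'b' -- and the phase vector theta in {+1, -1}^n is chosen to
maximize

    f(theta) = sum_{a,b} theta_a theta_b (w_ab + w_a'b' - w_a'b - w_ab')

so that same-haplotype sequences, which attract more cis Hi-C contacts, end
up with equal phase. The objective is invariant under a global sign flip;
a seeded multi-restart greedy-flip search finds the optimum (exact on small
instances, see tests). Blocks are phased per primary contig using all
contacts within the group; the same optimizer then clusters whole contigs
into the two output haplotype groups.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .model import Block, PhaseAssignment


class ContactMatrix:
    """Four Hi-C contact counts per unordered unit pair.

    ``w[(u, v)]`` with u < v is a 2x2 array indexed by [side_u][side_v];
    side 0 is the hap1 (alternate) sequence, side 1 the hap2 (primary) one.
    """

    def __init__(self):
        self.w: dict[tuple[str, str], np.ndarray] = {}

    def add(self, u: str, su: int, v: str, sv: int, n: int = 1) -> None:
        if u == v:
            raise ValueError("self-contact")
        if v < u:
            u, v, su, sv = v, u, sv, su
        mat = self.w.get((u, v))
        if mat is None:
            mat = self.w[(u, v)] = np.zeros((2, 2), dtype=np.int64)
        mat[su, sv] += n

    def net(self, u: str, v: str) -> int:
        """w_ab + w_a'b' - w_a'b - w_ab' for the pair."""
        if v < u:
            u, v = v, u
        mat = self.w.get((u, v))
        if mat is None:
            return 0
        return int(mat[0, 0] + mat[1, 1] - mat[1, 0] - mat[0, 1])

    def units(self) -> list[str]:
        seen = set()
        for u, v in self.w:
            seen.add(u)
            seen.add(v)
        return sorted(seen)


@dataclass
class RefIndex:
    """Maps (minced ref, position) -> (unit id, side), honouring sub-blocks."""

    intervals: dict[str, tuple[list[int], list[str], list[int]]] = field(default_factory=dict)
    unit_contig: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_blocks(cls, blocks: list[Block], pairing: dict[str, str]) -> "RefIndex":
        idx = cls()
        parent_base: dict[str, int] = {}
        for b in blocks:
            if b.parent_id is not None:
                cur = parent_base.get((b.parent_id, b.role))
                parent_base[(b.parent_id, b.role)] = (b.src_start if cur is None
                                                      else min(cur, b.src_start))
        per_ref: dict[str, list[tuple[int, str, int]]] = {}
        for b in blocks:
            if b.role == "collapsed":
                continue
            side = 0 if b.role == "hap1" else 1
            unit = b.block_id if b.role == "hap2" else pairing[b.block_id]
            if b.parent_id is None:
                ref, local = b.block_id, 0
            else:
                ref = b.parent_id
                local = b.src_start - parent_base[(b.parent_id, b.role)]
            per_ref.setdefault(ref, []).append((local, unit, side))
            idx.unit_contig[unit] = b.contig
        for ref, items in per_ref.items():
            items.sort()
            idx.intervals[ref] = ([s for s, _, _ in items], [u for _, u, _ in items],
                                  [sd for _, _, sd in items])
        return idx

    def lookup(self, ref: str, pos: int) -> tuple[str, int] | None:
        entry = self.intervals.get(ref)
        if entry is None:
            return None
        starts, units, sides = entry
        k = bisect_right(starts, pos) - 1
        if k < 0:
            k = 0
        return units[k], sides[k]


def count_contacts(pairs, blocks: list[Block], pairing: dict[str, str]
                   ) -> tuple[ContactMatrix, RefIndex, dict]:
    """Tally the four contact types from filtered mate-pairs.

    A mate is assigned to the sub-block containing its alignment start.
    Pairs touching collapsed sequence and pairs with both mates in one unit
    contribute nothing.
    """
    idx = RefIndex.from_blocks(blocks, pairing)
    cm = ContactMatrix()
    stats = {"counted": 0, "collapsed_skipped": 0, "same_unit": 0}
    for _, r1, s1, _, r2, s2, _ in pairs:
        hit1 = idx.lookup(r1, s1)
        hit2 = idx.lookup(r2, s2)
        if hit1 is None or hit2 is None:
            stats["collapsed_skipped"] += 1
            continue
        (u1, sd1), (u2, sd2) = hit1, hit2
        if u1 == u2:
            stats["same_unit"] += 1
            continue
        cm.add(u1, sd1, u2, sd2)
        stats["counted"] += 1
    return cm, idx, stats


def objective(theta: dict[str, int], contacts: ContactMatrix) -> int:
    total = 0
    for (u, v), mat in contacts.w.items():
        if u not in theta or v not in theta:
            raise KeyError(f"missing phase for {u if u not in theta else v}")
        net = int(mat[0, 0] + mat[1, 1] - mat[1, 0] - mat[0, 1])
        total += theta[u] * theta[v] * net
    return total


def optimize(contacts: ContactMatrix, seed: int, restarts: int = 100,
             max_rounds: int = 1000, units: list[str] | None = None,
             patience: int | None = None) -> PhaseAssignment:
    """Seeded multi-restart greedy flip search for the phase vector.

    Each restart draws a random +-1 vector, then repeatedly flips any unit
    whose flip increases the objective (gain computed incrementally from the
    unit's incident pairs) until a local optimum; the best local optimum
    across restarts wins. Restarting stops early after ``patience``
    consecutive restarts without improvement; small instances (<= 24 units)
    exhaust the full restart budget, where a single greedy descent can have
    a sizable failure probability that repetition drives to zero. The returned vector is
    canonicalized so its first unit has phase +1 (the objective is flip
    invariant), making the result deterministic given (contacts, seed).
    """
    if units is None:
        units = contacts.units()
    if not units:
        return PhaseAssignment(theta={}, objective=0, seed=seed, rounds=0)
    n = len(units)
    pos = {u: i for i, u in enumerate(units)}
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for (u, v), mat in contacts.w.items():
        net = int(mat[0, 0] + mat[1, 1] - mat[1, 0] - mat[0, 1])
        if net and u in pos and v in pos:
            adj[pos[u]].append((pos[v], net))
            adj[pos[v]].append((pos[u], net))
    flagged = [units[i] for i in range(n) if not adj[i]]
    if patience is None:
        patience = restarts if n <= 24 else 10

    rng = np.random.default_rng(seed)
    best_theta = np.ones(n, dtype=np.int64)
    best_obj = _objective_vec(best_theta, adj)
    rounds = 0
    stale = 0
    for _ in range(restarts):
        theta = rng.choice(np.array([1, -1], dtype=np.int64), size=n)
        obj = _objective_vec(theta, adj)
        for _ in range(max_rounds):
            rounds += 1
            improved = False
            for i in rng.permutation(n):
                gain = -2 * theta[i] * sum(theta[j] * w for j, w in adj[i])
                if gain > 0:
                    theta[i] = -theta[i]
                    obj += gain
                    improved = True
            if not improved:
                break
        if obj > best_obj:
            best_obj = obj
            best_theta = theta.copy()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best_theta[0] < 0:
        best_theta = -best_theta
    for i in range(n):
        if not adj[i]:
            best_theta[i] = 1  # tie: no contacts constrain this unit
    return PhaseAssignment(theta={u: int(best_theta[i]) for i, u in enumerate(units)},
                           objective=int(best_obj), seed=seed, rounds=rounds,
                           flagged=flagged)


def _objective_vec(theta: np.ndarray, adj) -> int:
    total = 0
    for i, edges in enumerate(adj):
        for j, w in edges:
            if j > i:
                total += int(theta[i]) * int(theta[j]) * w
    return total


def phase_groups(contacts: ContactMatrix, idx: RefIndex, seed: int,
                 restarts: int = 100) -> PhaseAssignment:
    """Phase every primary contig's units as one group, all contacts in play."""
    groups: dict[str, list[str]] = {}
    for unit, contig in idx.unit_contig.items():
        groups.setdefault(contig, []).append(unit)
    theta: dict[str, int] = {}
    total_obj = 0
    rounds = 0
    flagged: list[str] = []
    for k, contig in enumerate(sorted(groups)):
        members = sorted(groups[contig])
        sub = ContactMatrix()
        for (u, v), mat in contacts.w.items():
            if idx.unit_contig.get(u) == contig and idx.unit_contig.get(v) == contig:
                sub.w[(u, v)] = mat
        res = optimize(sub, seed=seed + k, restarts=restarts, units=members)
        theta.update(res.theta)
        total_obj += res.objective
        rounds += res.rounds
        flagged.extend(res.flagged)
    return PhaseAssignment(theta=theta, objective=total_obj, seed=seed,
                           rounds=rounds, flagged=flagged)


def dismiss_same_phase_switches(assignment: PhaseAssignment, blocks: list[Block],
                                pairing: dict[str, str]
                                ) -> tuple[list[Block], dict[str, str], dict[str, int], list[str]]:
    """Undo switch splits whose two sub-blocks got the same phase.

    Returns updated blocks, pairing, theta (merged units inherit the shared
    phase) and the list of dismissed parent block ids.
    """
    theta = dict(assignment.theta)
    sub_h2: dict[str, list[Block]] = {}
    for b in blocks:
        if b.parent_id is not None and b.role == "hap2":
            sub_h2.setdefault(b.parent_id, []).append(b)
    dismissed: list[str] = []
    drop: set[str] = set()
    merged: list[Block] = []
    new_pairing = dict(pairing)
    by_id = {b.block_id: b for b in blocks}
    for parent_id, subs in sorted(sub_h2.items()):
        if len(subs) < 2 or len({theta.get(s.block_id) for s in subs}) != 1:
            continue
        subs.sort(key=lambda b: b.start)
        phase = theta[subs[0].block_id]
        h1_subs = sorted((by_id[new_pairing[s.block_id]] for s in subs),
                         key=lambda b: b.src_start)
        h2_par = Block(parent_id, subs[0].contig, subs[0].start, subs[-1].end,
                       "hap2", None, subs[0].source, subs[0].src_start,
                       subs[-1].src_end, subs[0].strand)
        h1_par = Block(h1_subs[0].parent_id, h1_subs[0].contig, h2_par.start,
                       h2_par.end, "hap1", None, h1_subs[0].source,
                       h1_subs[0].src_start, h1_subs[-1].src_end, h1_subs[0].strand)
        h2_par.partner_id, h1_par.partner_id = h1_par.block_id, h2_par.block_id
        dismissed.extend([h2_par.block_id, h1_par.block_id])
        for s in subs + h1_subs:
            drop.add(s.block_id)
            new_pairing.pop(s.block_id, None)
            theta.pop(s.block_id, None)
        new_pairing[h1_par.block_id] = h2_par.block_id
        new_pairing[h2_par.block_id] = h1_par.block_id
        theta[h2_par.block_id] = phase
        merged.extend([h1_par, h2_par])
    out = [b for b in blocks if b.block_id not in drop] + merged
    out.sort(key=lambda b: (b.contig, b.start, b.role, b.src_start))
    return out, new_pairing, theta, dismissed


def contig_contacts(contacts: ContactMatrix, idx: RefIndex,
                    theta: dict[str, int]) -> ContactMatrix:
    """Aggregate block contacts to contig granularity.

    Side 0 of a contig unit is its per-contig haplotype 1 (the sequences
    routed there by theta: hap2 spans of +1 units plus hap1 spans of -1
    units); side 1 is haplotype 2.
    """
    cc = ContactMatrix()
    for (u, v), mat in contacts.w.items():
        cu, cv = idx.unit_contig.get(u), idx.unit_contig.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        tu, tv = theta.get(u), theta.get(v)
        if tu is None or tv is None:
            continue
        for su in (0, 1):
            for sv in (0, 1):
                n = int(mat[su, sv])
                if not n:
                    continue
                # block side -> per-contig haplotype: theta=+1 sends hap2 (side 1) to hap 1
                hu = 0 if (su == 1) == (tu == 1) else 1
                hv = 0 if (sv == 1) == (tv == 1) else 1
                cc.add(cu, hu, cv, hv, n)
    return cc


def cluster_contigs(cc: ContactMatrix, contigs: list[str], seed: int,
                    restarts: int = 100) -> tuple[dict[str, str], list[str]]:
    """Assign every contig's per-contig haplotype 1 to group H1 or H2."""
    res = optimize(cc, seed=seed, restarts=restarts, units=sorted(contigs))
    groups = {c: ("H1" if t == 1 else "H2") for c, t in res.theta.items()}
    return groups, res.flagged


def write_phases_tsv(path, theta: dict[str, int], groups: dict[str, str],
                     unit_contig: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("#block_id\ttheta\tgroup\n")
        for unit in sorted(theta):
            grp = groups.get(unit_contig.get(unit, ""), "H1")
            fh.write(f"{unit}\t{theta[unit]}\t{grp}\n")


def read_phases_tsv(path) -> tuple[dict[str, int], dict[str, str]]:
    theta: dict[str, int] = {}
    grp: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            unit, t, g = line.split()
            theta[unit] = int(t)
            grp[unit] = g
    return theta, grp
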