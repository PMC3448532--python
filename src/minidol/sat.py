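"""A compact CDCL propositional satisfiability solver.

Conflict-driven clause learning with first-UIP resolution, non-chronological
backjumping, two watched literals, VSIDS-style activity ordering and
optional phase hints.  The clause store and watch lists persist across
:meth:`solve` calls (clauses only accumulate), which suits the reasoner's
pattern of many queries against one grounding, with goals and learned
cones toggled through assumptions.

Problem sizes produced by grounding desk-scale ontologies over domains of
at most eight elements stay in the low thousands of variables, well within
reach of this solver.

Literals are non-zero integers: ``v`` for a positive occurrence of
variable ``v`` (1-based), ``-v`` for a negative one.
"""

from __future__ import annotations

from typing import Iterable, Optional

__all__ = ["Solver"]

_UNASSIGNED = -1


class Solver:
    def __init__(self):
        self.num_vars = 0
        self.clauses: list = []
        self._watches: dict = {}
        self._units: list = []
        self._empty_clause = False

    def new_var(self) -> int:
        self.num_vars += 1
        return self.num_vars

    def ensure_var(self, v: int) -> None:
        if v > self.num_vars:
            self.num_vars = v

    def add_clause(self, lits: Iterable[int]) -> None:
        clause = []
        seen = set()
        for lit in lits:
            if lit == 0:
                raise ValueError("0 is not a literal")
            if -lit in seen:
                return  # tautology, drop
            if lit in seen:
                continue
            seen.add(lit)
            clause.append(lit)
            self.ensure_var(abs(lit))
        if not clause:
            self._empty_clause = True
            return
        if len(clause) == 1:
            self._units.append(clause[0])
            return
        self._attach(clause)

    def _attach(self, clause: list) -> None:
        ci = len(self.clauses)
        self.clauses.append(clause)
        self._watches.setdefault(clause[0], []).append(ci)
        self._watches.setdefault(clause[1], []).append(ci)

    def solve(self, assumptions: Iterable[int] = (),
              phase: Optional[dict] = None,
              keep_guard: Optional[list] = None) -> Optional[list]:
        """Return ``assignment`` (index ``v`` in ``1..num_vars`` holds a
        bool; index 0 unused) or ``None`` when unsatisfiable under the
        assumptions.  ``phase`` optionally suggests the value first tried
        when branching (default False: smallest extensions first, which
        suits grounded structural constraints).

        Assumptions are pseudo-decisions, so clauses learned during the
        call may depend on them; by default they are discarded when the
        call ends.  When ``keep_guard`` is given (normally the negations
        of the assumptions), learned clauses are retained with the guard
        literals appended, which makes them valid unconditionally."""
        if self._empty_clause:
            return None
        n = self.num_vars
        clauses = self.clauses
        n_permanent = len(clauses)
        watches = self._watches

        assign = [_UNASSIGNED] * (n + 1)
        level = [0] * (n + 1)
        reason = [-1] * (n + 1)
        trail: list = []
        trail_lim: list = []
        qhead = 0

        activity = [0.0] * (n + 1)
        var_inc = 1.0

        def value(lit: int) -> int:
            v = assign[abs(lit)]
            if v == _UNASSIGNED:
                return _UNASSIGNED
            return v if lit > 0 else 1 - v

        def enqueue(lit: int, res: int) -> bool:
            v = value(lit)
            if v == 1:
                return True
            if v == 0:
                return False
            var = abs(lit)
            assign[var] = 1 if lit > 0 else 0
            level[var] = len(trail_lim)
            reason[var] = res
            trail.append(lit)
            return True

        def propagate() -> int:
            """Return conflicting clause index, or -1."""
            nonlocal qhead
            while qhead < len(trail):
                lit = trail[qhead]
                qhead += 1
                falsified = -lit
                wl = watches.get(falsified)
                if not wl:
                    continue
                j = 0
                while j < len(wl):
                    ci = wl[j]
                    cl = clauses[ci]
                    if cl[0] == falsified:
                        cl[0], cl[1] = cl[1], cl[0]
                    if value(cl[0]) == 1:
                        j += 1
                        continue
                    moved = False
                    for k in range(2, len(cl)):
                        if value(cl[k]) != 0:
                            cl[1], cl[k] = cl[k], cl[1]
                            watches.setdefault(cl[1], []).append(ci)
                            wl[j] = wl[-1]
                            wl.pop()
                            moved = True
                            break
                    if moved:
                        continue
                    if value(cl[0]) == 0:
                        return ci
                    enqueue(cl[0], ci)
                    j += 1
            return -1

        def bump(v: int) -> None:
            nonlocal var_inc
            activity[v] += var_inc

        def decay() -> None:
            nonlocal var_inc
            var_inc /= 0.95
            if var_inc > 1e100:
                for i in range(n + 1):
                    activity[i] *= 1e-100
                var_inc *= 1e-100

        def analyze(confl: int):
            """First-UIP conflict analysis; returns (learned, backlevel)."""
            cur_level = len(trail_lim)
            learned = []
            seen = [False] * (n + 1)
            counter = 0
            p = 0  # literal being resolved on (0 = start with whole clause)
            idx = len(trail) - 1
            cl = clauses[confl]
            while True:
                start = 0 if p == 0 else 1
                # cl[0] is the asserted literal when p != 0
                lits = cl if p == 0 else cl[1:] if cl[0] == p else \
                    [x for x in cl if x != p]
                for q in lits:
                    var = abs(q)
                    if seen[var]:
                        continue
                    seen[var] = True
                    bump(var)
                    if level[var] >= cur_level:
                        counter += 1
                    elif level[var] > 0:
                        learned.append(q)
                # find next literal at current level on trail
                while not seen[abs(trail[idx])]:
                    idx -= 1
                p_lit = trail[idx]
                var = abs(p_lit)
                seen[var] = False
                counter -= 1
                idx -= 1
                if counter == 0:
                    learned.insert(0, -p_lit)
                    break
                cl = clauses[reason[var]]
                p = p_lit
            if len(learned) == 1:
                back = 0
            else:
                back = max(level[abs(q)] for q in learned[1:])
                # move a literal of back level to position 1
                for k in range(1, len(learned)):
                    if level[abs(learned[k])] == back:
                        learned[1], learned[k] = learned[k], learned[1]
                        break
            return learned, back

        def cancel_until(lvl: int) -> None:
            nonlocal qhead
            if len(trail_lim) <= lvl:
                return
            lim = trail_lim[lvl]
            for lit in trail[lim:]:
                assign[abs(lit)] = _UNASSIGNED
            del trail[lim:]
            del trail_lim[lvl:]
            qhead = len(trail)

        result: Optional[list] = None
        learned_records: list = []
        try:
            for u in self._units:
                if not enqueue(u, -1):
                    return None
            if propagate() != -1:
                return None
            root = len(trail)  # units fixed forever this call

            # assumptions as pseudo-decisions
            for a in assumptions:
                if abs(a) > n:
                    continue
                if value(a) == 1:
                    continue
                if value(a) == 0:
                    return None
                trail_lim.append(len(trail))
                enqueue(a, -1)
                if propagate() != -1:
                    return None
            n_assumption_levels = len(trail_lim)

            order = sorted(range(1, n + 1), key=lambda v: -activity[v])
            reorder_countdown = 0

            while True:
                confl = propagate()
                if confl != -1:
                    if len(trail_lim) <= n_assumption_levels:
                        return None
                    learned, back = analyze(confl)
                    learned_records.append(list(learned))
                    back = max(back, n_assumption_levels)
                    cancel_until(back)
                    decay()
                    if len(learned) == 1:
                        if not enqueue(learned[0], -1):
                            return None
                    else:
                        self._attach(learned)
                        enqueue(learned[0], len(clauses) - 1)
                    reorder_countdown -= 1
                    if reorder_countdown <= 0:
                        order = sorted(range(1, n + 1),
                                       key=lambda v: -activity[v])
                        reorder_countdown = 256
                    continue
                decision = None
                for v in order:
                    if assign[v] == _UNASSIGNED:
                        decision = v
                        break
                if decision is None:
                    result = [False] + [assign[v] == 1
                                        for v in range(1, n + 1)]
                    return result
                first = False if phase is None else \
                    bool(phase.get(decision, False))
                trail_lim.append(len(trail))
                enqueue(decision if first else -decision, -1)
        finally:
            # learned clauses may depend on this call's assumptions; drop
            # them (and their watches), then optionally re-add guarded
            # versions that are valid unconditionally
            for ci in range(len(clauses) - 1, n_permanent - 1, -1):
                cl = clauses[ci]
                for w in (cl[0], cl[1]):
                    wl = self._watches.get(w)
                    if wl is not None:
                        try:
                            wl.remove(ci)
                        except ValueError:
                            pass
                clauses.pop()
            if keep_guard is not None:
                for rec in learned_records:
                    self.add_clause(rec + list(keep_guard))
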