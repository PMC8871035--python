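"""Joint progressive type-II censoring (JPC) of two pooled samples.

Two samples — A with ``m`` units and B with ``n`` units — are placed on test
together.  At the i-th observed failure time ``w_i`` a prefixed number
``r_i`` of surviving units is withdrawn at random from the pool; ``s_i`` of
them happen to come from A and ``t_i = r_i - s_i`` from B.  The indicator
``z_i`` records whether the i-th failure itself came from A.  The experiment
stops at the k-th failure, where every remaining survivor is withdrawn, so
the removal numbers satisfy sum(r_i + 1) = m + n.

The removal counts r_i are part of the design; which particular survivors
get withdrawn is random.  Here withdrawal is uniform simple random sampling
without replacement from the pooled survivors, so (s_i, t_i) is a
hypergeometric split of r_i.  The likelihood of the observed record does not
depend on this choice.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np

from .distribution import IERDParams, rvs

__all__ = [
    "JPCDesign",
    "JPCData",
    "parse_scheme",
    "format_scheme",
    "apply_jpc",
    "simulate_jpc",
    "write_jpc",
    "read_jpc",
]

_TOKEN = re.compile(r"^\s*(\d+)\s*(?:\^\s*(\d+)|\(\s*(\d+)\s*\))?\s*$")


def parse_scheme(text: str, k: int | None = None) -> np.ndarray:
    """Expand a compact removal-pattern string into a removals vector.

    Both ``"(0^9,25,0^10)"`` and the ``"(0(9),25,0(10))"`` styles are
    accepted: a token ``a^b`` or ``a(b)`` repeats the removal count ``a``
    for ``b`` successive failures.  If ``k`` is given, the expanded length
    must equal it.
    """
    body = text.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    # split on commas that are not inside a repeat-count parenthesis
    parts, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    out: list[int] = []
    for part in parts:
        mtch = _TOKEN.match(part)
        if not mtch:
            raise ValueError(f"malformed scheme token {part!r} in {text!r}")
        val = int(mtch.group(1))
        rep = mtch.group(2) or mtch.group(3)
        out.extend([val] * (int(rep) if rep else 1))
    r = np.asarray(out, dtype=int)
    if np.any(r < 0):
        raise ValueError(f"negative removal count in {text!r}")
    if k is not None and len(r) != k:
        raise ValueError(f"scheme {text!r} expands to length {len(r)}, expected k={k}")
    return r


def format_scheme(removals) -> str:
    """Compact run-length string for a removals vector, e.g. ``(5,0^28,10)``."""
    r = np.asarray(removals, dtype=int)
    toks = []
    i = 0
    while i < len(r):
        j = i
        while j < len(r) and r[j] == r[i]:
            j += 1
        run = j - i
        toks.append(f"{r[i]}^{run}" if run > 1 else f"{r[i]}")
        i = j
    return "(" + ",".join(toks) + ")"


@dataclass(frozen=True)
class JPCDesign:
    """The censoring plan: sample sizes, failure count, removal vector."""

    m: int
    n: int
    k: int
    removals: tuple[int, ...]

    def __post_init__(self) -> None:
        if isinstance(self.removals, str):
            object.__setattr__(
                self, "removals", tuple(int(v) for v in parse_scheme(self.removals, self.k))
            )
        else:
            object.__setattr__(self, "removals", tuple(int(v) for v in self.removals))
        if self.m < 1 or self.n < 1 or self.k < 1:
            raise ValueError("m, n, k must be positive integers")
        if self.k > self.m + self.n:
            raise ValueError("k cannot exceed m + n")
        r = np.asarray(self.removals)
        if len(r) != self.k:
            raise ValueError(f"removals has length {len(r)}, expected k={self.k}")
        if np.any(r < 0):
            raise ValueError("removal counts must be non-negative")
        if int(np.sum(r + 1)) != self.m + self.n:
            raise ValueError(
                f"sum(r_i + 1) = {int(np.sum(r + 1))} must equal m + n = {self.m + self.n}"
            )

    @property
    def scheme(self) -> str:
        return format_scheme(self.removals)


@dataclass(frozen=True)
class JPCData:
    """One observed JPC record: (w_i, s_i, t_i, z_i) rows plus the design."""

    w: np.ndarray
    s: np.ndarray
    t: np.ndarray
    z: np.ndarray
    design: JPCDesign

    def __post_init__(self) -> None:
        for name in ("w", "s", "t", "z"):
            object.__setattr__(
                self,
                name,
                np.asarray(getattr(self, name), dtype=float if name == "w" else int),
            )
        d = self.design
        if not (len(self.w) == len(self.s) == len(self.t) == len(self.z) == d.k):
            raise ValueError("w, s, t, z must all have length k")
        if np.any(self.w <= 0):
            raise ValueError("failure times must be positive")
        if np.any(np.diff(self.w) < 0):
            raise ValueError("failure times must be non-decreasing")
        if not np.all(np.isin(self.z, (0, 1))):
            raise ValueError("z entries must be 0 or 1")
        if np.any(self.s < 0) or np.any(self.t < 0):
            raise ValueError("withdrawal counts must be non-negative")
        r = np.asarray(d.removals)
        if np.any(self.s + self.t != r):
            raise ValueError("s_i + t_i must equal r_i for every i")
        if int(np.sum(self.z + self.s)) > d.m:
            raise ValueError("sample A accounting exceeds m")
        if int(np.sum(1 - self.z + self.t)) > d.n:
            raise ValueError("sample B accounting exceeds n")

    @property
    def k1(self) -> int:
        """Number of observed failures attributable to sample A."""
        return int(np.sum(self.z))

    @property
    def k2(self) -> int:
        """Number of observed failures attributable to sample B."""
        return int(self.design.k - self.k1)

    @property
    def is_degenerate(self) -> bool:
        """True when every failure came from one sample; MLEs then do not exist."""
        return self.k1 == 0 or self.k2 == 0


def apply_jpc(lifetimesA, lifetimesB, design: JPCDesign, seed=None) -> JPCData:
    """Censor two complete samples according to ``design``.

    At each failure the smallest remaining lifetime is observed; ties are
    broken by stable input order with sample A before sample B, which is
    deterministic and seed-independent.  The randomness (which survivors are
    withdrawn) is driven by ``seed``.
    """
    a = np.asarray(lifetimesA, dtype=float)
    b = np.asarray(lifetimesB, dtype=float)
    if len(a) != design.m or len(b) != design.n:
        raise ValueError("lifetime vectors must have lengths (m, n)")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("lifetimes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pool = np.concatenate([a, b])
    is_a = np.concatenate([np.ones(design.m, bool), np.zeros(design.n, bool)])
    # stable ascending order: equal values keep input order, A first
    order = np.argsort(pool, kind="stable")
    alive = list(order)  # indices into pool, sorted by lifetime

    w = np.empty(design.k)
    s = np.zeros(design.k, int)
    t = np.zeros(design.k, int)
    z = np.zeros(design.k, int)
    for i, ri in enumerate(design.removals):
        idx = alive.pop(0)  # smallest remaining lifetime fails
        w[i] = pool[idx]
        z[i] = int(is_a[idx])
        if ri > 0:
            chosen = rng.choice(len(alive), size=ri, replace=False)
            chosen_idx = [alive[c] for c in chosen]
            s[i] = int(np.sum(is_a[chosen_idx]))
            t[i] = ri - s[i]
            for c in sorted(chosen, reverse=True):
                alive.pop(c)
    assert not alive, "design invariant sum(r_i + 1) = m + n guarantees exhaustion"
    return JPCData(w=w, s=s, t=t, z=z, design=design)


def simulate_jpc(design: JPCDesign, pA: IERDParams, pB: IERDParams, seed=None) -> JPCData:
    """Draw IERD lifetimes for both samples and censor them under ``design``.

    Degenerate outcomes (all failures from one sample) are returned as-is
    with :attr:`JPCData.is_degenerate` set; callers decide whether to redraw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rvs(design.m, pA, rng)
    b = rvs(design.n, pB, rng)
    return apply_jpc(a, b, design, rng)


def write_jpc(data: JPCData, path_or_buf) -> None:
    """Serialize a JPC record as TSV with a ``#JPC`` design header line."""
    d = data.design
    header = f"#JPC m={d.m} n={d.n} k={d.k} r={','.join(str(v) for v in d.removals)}\n"
    rows = "".join(
        f"{data.w[i]:.17g}\t{data.s[i]}\t{data.t[i]}\t{data.z[i]}\n" for i in range(d.k)
    )
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header + rows)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header + rows)


def read_jpc(path_or_buf) -> JPCData:
    """Parse the TSV dialect written by :func:`write_jpc`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#JPC"):
        raise ValueError("missing '#JPC' design header line")
    fields = dict(tok.split("=", 1) for tok in lines[0][4:].split())
    design = JPCDesign(
        m=int(fields["m"]),
        n=int(fields["n"]),
        k=int(fields["k"]),
        removals=tuple(int(v) for v in fields["r"].split(",")),
    )
    body = np.loadtxt(io.StringIO("\n".join(lines[1:])), ndmin=2)
    if body.shape != (design.k, 4):
        raise ValueError(f"expected {design.k} rows of (w, s, t, z)")
    return JPCData(w=body[:, 0], s=body[:, 1], t=body[:, 2], z=body[:, 3], design=design)
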