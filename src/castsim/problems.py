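"""Synthetic problem banks: difficulty-sorted pools of math and word items.

Items live on a continuous latent-difficulty scale whose canonical mapping
is ``latent_difficulty = level`` (levels 1..7, 1 easiest) plus a small
level-internal spread.  Only the ordering of the levels and the agent
psychometric mapping matter downstream, so the parametric family is kept
deliberately simple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ResourceExhaustedError

DOMAINS = ("math", "word")
MIN_LEVEL = 1
MAX_LEVEL = 7
LEVELS = tuple(range(MIN_LEVEL, MAX_LEVEL + 1))

#: SD of latent difficulty within one level cell.
LATENT_SD = 0.15


def latent_difficulty_of_level(level: int) -> float:
    """Canonical location of a difficulty level on the latent scale."""
    return float(level)


@dataclass(frozen=True)
class ProblemSpec:
    """One solvable item."""

    id: str
    domain: str
    level: int
    latent_difficulty: float

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise InvalidArgumentError(f"unknown domain {self.domain!r}")
        if not MIN_LEVEL <= self.level <= MAX_LEVEL:
            raise InvalidArgumentError(f"level {self.level} outside [{MIN_LEVEL}, {MAX_LEVEL}]")


class ProblemBank:
    """Collection of :class:`ProblemSpec` keyed by ``(domain, level)``."""

    def __init__(self, problems):
        self._cells: dict[tuple[str, int], list[ProblemSpec]] = {}
        seen = set()
        for p in problems:
            if p.id in seen:
                raise InvalidArgumentError(f"duplicate problem id {p.id!r}")
            seen.add(p.id)
            self._cells.setdefault((p.domain, p.level), []).append(p)

    def counts(self) -> dict[tuple[str, int], int]:
        return {k: len(v) for k, v in self._cells.items()}

    def cell(self, domain: str, level: int) -> list[ProblemSpec]:
        return list(self._cells.get((domain, level), []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._cells.values())

    def sampler(self) -> "BankSampler":
        """Fresh per-session draw state (without-replacement with reset)."""
        return BankSampler(self)

    # -- CSV round trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.id, p.domain, p.level, p.latent_difficulty)
            for cell in self._cells.values()
            for p in cell
        ]
        return pd.DataFrame(rows, columns=["id", "domain", "level", "latent_difficulty"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProblemBank":
        df = pd.read_csv(path)
        return cls(
            ProblemSpec(str(r.id), r.domain, int(r.level), float(r.latent_difficulty))
            for r in df.itertuples()
        )


class BankSampler:
    """Session-scoped sampling discipline over a bank.

    Draws are without replacement within a session until a cell is
    exhausted, at which point the cell resets — repeats are possible but
    maximally delayed.
    """

    def __init__(self, bank: ProblemBank):
        self._bank = bank
        self._pools: dict[tuple[str, int], list[ProblemSpec]] = {}

    def draw(self, domain: str, level: int, rng) -> ProblemSpec:
        key = (domain, level)
        pool = self._pools.get(key)
        if not pool:
            fresh = self._bank.cell(domain, level)
            if not fresh:
                raise ResourceExhaustedError(f"empty problem cell {key}")
            rng.shuffle(fresh)
            pool = self._pools[key] = fresh
        return pool.pop()


def _allocate_levels(n: int) -> list[int]:
    """Near-uniform allocation of n items over the 7 levels, remainder to lower levels."""
    base, rem = divmod(n, len(LEVELS))
    return [base + (1 if i < rem else 0) for i in range(len(LEVELS))]


def generate_bank(n_math: int, n_word: int, seed: int) -> ProblemBank:
    """Generate a difficulty-sorted synthetic bank.

    Latent difficulties are drawn from level-indexed normal distributions
    (location = level, scale = :data:`LATENT_SD`), so mean latent
    difficulty is strictly increasing in level. Deterministic given seed.
    """
    if n_math < 0 or n_word < 0:
        raise InvalidArgumentError("item counts must be non-negative")
    rng = np.random.default_rng(seed)
    problems = []
    for domain, total in (("math", n_math), ("word", n_word)):
        counts = _allocate_levels(total)
        idx = 0
        for level, count in zip(LEVELS, counts):
            lat = latent_difficulty_of_level(level) + LATENT_SD * rng.standard_normal(count)
            for d in lat:
                problems.append(ProblemSpec(f"{domain}-{idx:05d}", domain, level, float(d)))
                idx += 1
    return ProblemBank(problems)


def draw_problem(sampler: BankSampler, domain: str, level: int, rng) -> ProblemSpec:
    """Draw one item of the requested cell from a session sampler."""
    return sampler.draw(domain, level, rng)


# ---------------------------------------------------------------------------
# Concrete math item rendering (missing-digit multiplication)

#: operand digit counts per level; total digits grow with level
_DIGITS_BY_LEVEL = {1: (1, 1), 2: (2, 1), 3: (2, 1), 4: (2, 2), 5: (3, 2), 6: (3, 3), 7: (4, 3)}

BLANK = "▢"  # white square placeholder


@dataclass(frozen=True)
class RenderedItem:
    statement: str
    options: tuple[str, str, str]
    answer_index: int

    @property
    def answer(self) -> str:
        return self.options[self.answer_index]


def render_equation(a: int, b: int, blank_pos: int, rng) -> RenderedItem:
    """Render ``a x b`` with one product digit blanked and a 3-option bank."""
    product = str(a * b)
    if not 0 <= blank_pos < len(product):
        raise InvalidArgumentError(f"blank position {blank_pos} outside product {product!r}")
    correct = product[blank_pos]
    shown = product[:blank_pos] + BLANK + product[blank_pos + 1 :]
    decoys = [d for d in "0123456789" if d != correct]
    rng.shuffle(decoys)
    options = [correct, decoys[0], decoys[1]]
    rng.shuffle(options)
    return RenderedItem(
        statement=f"{a} × {b} = {shown}",
        options=tuple(options),
        answer_index=options.index(correct),
    )


def render_math_item(level: int, rng) -> RenderedItem:
    """Render a missing-digit multiplication whose operand size grows with level."""
    if not MIN_LEVEL <= level <= MAX_LEVEL:
        raise InvalidArgumentError(f"level {level} outside [{MIN_LEVEL}, {MAX_LEVEL}]")
    da, db = _DIGITS_BY_LEVEL[level]
    a = rng.randrange(10 ** (da - 1), 10**da)
    b = rng.randrange(10 ** (db - 1), 10**db)
    if level == 1 and a * b < 10:  # keep at least two product digits to blank
        a, b = max(a, 4), max(b, 3)
    product_len = len(str(a * b))
    return render_equation(a, b, rng.randrange(product_len), rng)
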