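"""Convert a mismatch expansion parameter tau into generations and years.

tau is the expansion age in mutational time, tau = 2 * mu_hap * t, where
mu_hap is the per-generation mutation rate of the whole haplotype.  With a
per-site rate mu_site and a fragment of L nt, mu_hap = mu_site * L, so

    t = tau / (2 * mu_site * L)   generations.

Calendar ages follow from a generations-per-year range: organisms with
g generations per year expanded t / g years ago, so a (low, high) range
of generation rates maps t to the interval (t / high, t / low).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class ExpansionTime:
    tau: float
    mu_site: float
    L: int
    generations: float
    gen_per_year: tuple[float, float]
    years: tuple[float, float]

    @property
    def generations_rounded(self) -> int:
        return round_to_thousand(self.generations)

    @property
    def years_rounded(self) -> tuple[int, int]:
        """Year interval derived from the report-rounded generation count
        (the convention of the headline worked example: 44,000 generations
        at 2-5 generations/year gives 8,800-22,000 years)."""
        low, high = self.gen_per_year
        gr = self.generations_rounded
        return int(round(gr / high)), int(round(gr / low))


def round_to_thousand(x: float) -> int:
    """Report-level rounding to the nearest 1,000 (raw values stay in JSON)."""
    return int(round(x / 1000.0)) * 1000


def tau_to_generations(tau: float, mu_site: float, L: int) -> float:
    """Generations since expansion: t = tau / (2 * mu_site * L)."""
    if tau <= 0 or mu_site <= 0 or L <= 0:
        raise DomainError("tau, mu_site and L must all be positive")
    return tau / (2.0 * mu_site * L)


def generations_to_years(t: float, gen_per_year: tuple[float, float]) -> tuple[float, float]:
    """Calendar-year interval (t / high, t / low) for a generation-rate range."""
    low, high = gen_per_year
    if t < 0:
        raise DomainError("generations must be non-negative")
    if low <= 0 or high <= 0 or low > high:
        raise DomainError("need 0 < low <= high generations per year")
    return (t / high, t / low)


def expansion_time(
    tau: float,
    mu_site: float,
    L: int,
    gen_per_year: tuple[float, float] = (2.0, 5.0),
) -> ExpansionTime:
    t = tau_to_generations(tau, mu_site, L)
    return ExpansionTime(
        tau=tau,
        mu_site=mu_site,
        L=L,
        generations=t,
        gen_per_year=gen_per_year,
        years=generations_to_years(t, gen_per_year),
    )
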