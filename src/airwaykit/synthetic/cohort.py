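"""Summary-level paired-scan cohorts with known measurement noise.

Simulating full repeat CT scans for hundreds of participants is unnecessary
for validating the agreement statistics: what the statistics consume are
per-scan generation means (LA, WAP) and Pi10.  This generator draws a
population of participants with realistic between-subject spread, then adds
independent per-scan measurement noise with known per-generation SDs, so the
recovered Bland-Altman limits of agreement can be checked against the
closed-form ``1.96 * sqrt(2) * sigma_g``.

By default the injected noise is moment-matched: each noise vector is
centred, the two scans' noise vectors are decorrelated, and both are rescaled
to the nominal sample SD, so the simulated cohort realises the specified
noise level exactly at finite n rather than only in expectation.
"""

from __future__ import annotations

import numpy as np

from ..measure import ScanSummary
from ..repro import PairedCohort, Participant

__all__ = ["simulate_summary_cohort", "DEFAULT_LA_MEAN", "DEFAULT_LA_NOISE_SD"]

# Generation-wise population means for a general screening population:
# luminal area (mm^2) falls roughly geometrically from the trachea outward,
# wall area percentage rises as airways narrow.
DEFAULT_LA_MEAN = {0: 250.0, 1: 120.0, 2: 65.0, 3: 42.0, 4: 26.0, 5: 17.0, 6: 11.0}
DEFAULT_WAP_MEAN = {0: 30.0, 1: 38.0, 2: 48.0, 3: 56.0, 4: 60.0, 5: 63.0, 6: 65.0}
# Per-scan measurement noise SDs (same units as the parameter).
DEFAULT_LA_NOISE_SD = {0: 13.0, 1: 6.0, 2: 7.0, 3: 3.3, 4: 2.3, 5: 1.6, 6: 1.3}
DEFAULT_WAP_NOISE_SD = {0: 0.5, 1: 0.85, 2: 1.4, 3: 1.5, 4: 1.6, 5: 1.5, 6: 1.45}


def _matched_noise_pair(rng: np.random.Generator, n: int, sd: float):
    """Two noise vectors with exactly zero mean, zero cross-correlation and
    sample SD ``sd`` (ddof=1)."""
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    e1 -= e1.mean()
    e2 -= e2.mean()
    e2 -= (e2 @ e1) / (e1 @ e1) * e1
    e1 *= sd / e1.std(ddof=1)
    e2 *= sd / e2.std(ddof=1)
    return e1, e2


def simulate_summary_cohort(
    n_participants: int = 100,
    la_mean: dict[int, float] | None = None,
    la_noise_sd: dict[int, float] | None = None,
    wap_mean: dict[int, float] | None = None,
    wap_noise_sd: dict[int, float] | None = None,
    la_between_sd_frac: float = 0.20,
    wap_between_sd: float = 3.4,
    pi10_mean: float = 3.9,
    pi10_between_sd: float = 0.12,
    pi10_noise_sd: float = 0.035,
    tlv_mean_l: float = 5.5,
    tlv_between_sd_l: float = 1.3,
    tlv_drift_sd: float = 0.0,
    missing_rate: float = 0.0,
    exact_moments: bool = True,
    seed: int = 0,
) -> tuple[PairedCohort, dict[int, float]]:
    """Simulate a paired-scan cohort at the scan-summary level.

    Returns ``(cohort, la_noise_sd)`` so callers can compare recovered limits
    of agreement with the injected per-generation noise.  ``tlv_drift_sd``
    adds a random relative inspiration change between scans (default 0:
    inspiration-matched by design; the TLV exclusion rule is exercised by
    passing a non-zero drift).  ``missing_rate`` drops a generation from one
    scan of a participant with the given probability, exercising pairwise
    deletion in the report.
    """
    rng = np.random.default_rng(seed)
    la_mean = dict(DEFAULT_LA_MEAN if la_mean is None else la_mean)
    la_noise_sd = dict(DEFAULT_LA_NOISE_SD if la_noise_sd is None else la_noise_sd)
    wap_mean = dict(DEFAULT_WAP_MEAN if wap_mean is None else wap_mean)
    wap_noise_sd = dict(DEFAULT_WAP_NOISE_SD if wap_noise_sd is None else wap_noise_sd)
    gens = sorted(la_mean)
    n = n_participants

    la_true = {g: la_mean[g] * (1.0 + la_between_sd_frac * rng.standard_normal(n)) for g in gens}
    wap_true = {g: wap_mean[g] + wap_between_sd * rng.standard_normal(n) for g in gens}
    pi10_true = pi10_mean + pi10_between_sd * rng.standard_normal(n)
    tlv1 = np.clip(tlv_mean_l + tlv_between_sd_l * rng.standard_normal(n), 2.0, None)
    tlv2 = tlv1 * (1.0 + tlv_drift_sd * rng.standard_normal(n)) if tlv_drift_sd > 0 else tlv1.copy()

    def noise(sd: float):
        if exact_moments:
            return _matched_noise_pair(rng, n, sd)
        return sd * rng.standard_normal(n), sd * rng.standard_normal(n)

    la_e = {g: noise(la_noise_sd[g]) for g in gens}
    wap_e = {g: noise(wap_noise_sd[g]) for g in gens}
    pi10_e = noise(pi10_noise_sd)

    participants = []
    for i in range(n):
        scans = []
        for s in (0, 1):
            la = {g: float(la_true[g][i] + la_e[g][s][i]) for g in gens}
            wap = {g: float(wap_true[g][i] + wap_e[g][s][i]) for g in gens}
            if missing_rate > 0:
                for g in list(la):
                    if g > 0 and rng.uniform() < missing_rate:
                        la.pop(g)
                        wap.pop(g)
            scans.append(
                ScanSummary(
                    mean_la_by_generation=la,
                    mean_wap_by_generation=wap,
                    pi10_mm=float(pi10_true[i] + pi10_e[s][i]),
                    tac=int(rng.integers(180, 320)),
                    tlv_l=float((tlv1 if s == 0 else tlv2)[i]),
                    max_generation=max(la),
                )
            )
        participants.append(
            Participant(participant_id=f"P{i:03d}", scan1=scans[0], scan2=scans[1])
        )
    return PairedCohort(participants=participants), la_noise_sd
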