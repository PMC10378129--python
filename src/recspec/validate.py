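"""Cross-oracle validation suite.

Runs every pairwise consistency check the package's design rests on, each on
freshly generated seeded fixtures, and reports maximum deviations:

* closed form vs forward substitution (exact arithmetic);
* continued-fraction / orthogonal-polynomial rational identity;
* quantization-polynomial spectra vs dense tridiagonal eigenvalues;
* Heun series vs ODE residual;
* spectral time evolution vs matrix exponential.

The report is plain JSON; any failed property makes ``passed`` False (the
CLI exits non-zero in that case).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .contfrac import rational_identity_gap
from .exceptions import PoleError
from .fixtures import FixtureSpec, random_heun_params, random_recurrence
from .heun import heun_series, ode_residual
from .models import BinaryChoiceModel, binary_choice_generator
from .recurrence import closed_form_C, forward_substitution
from .spectral import dense_spectrum_oracle, eigen_spectrum, evolve, matrix_exponential_oracle

__all__ = ["run_validation_suite", "default_config"]


def default_config() -> dict:
    return {
        "seed": 0,
        "closed_form": {"families": 25, "i_max": 20},
        "identity": {"families": 10, "N": 8, "q_draws": 4},
        "spectrum": {"models": 6, "N": [3, 5, 8]},
        "heun": {"draws": 10, "order": 40},
        "evolve": {"models": 3, "N": 12, "times": [0.1, 1.0, 10.0]},
    }


def run_validation_suite(config: dict | None = None) -> dict:
    cfg = default_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and k in cfg:
                cfg[k].update(v)
            else:
                cfg[k] = v
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    props = []

    # 1. closed form == forward substitution, exact arithmetic
    n_fam = cfg["closed_form"]["families"]
    i_max = cfg["closed_form"]["i_max"]
    exact_ok = True
    for k in range(n_fam):
        rec = random_recurrence(FixtureSpec("random_recurrence", seed=seed * 1000 + k,
                                            size=i_max, exact=True))
        C = forward_substitution(rec, i_max)
        for i in range(i_max + 1):
            if closed_form_C(rec, i) != C[i]:
                exact_ok = False
    props.append({"property": "closed_form_equals_forward_substitution",
                  "samples": n_fam * (i_max + 1), "max_deviation": 0.0 if exact_ok else None,
                  "passed": exact_ok})

    # 2. continued-fraction rational identity
    idc = cfg["identity"]
    worst_gap = 0.0
    checked = 0
    for k in range(idc["families"]):
        rec = random_recurrence(FixtureSpec("random_recurrence", seed=seed * 2000 + k,
                                            size=idc["N"] + 1, exact=True))
        for _ in range(idc["q_draws"]):
            from fractions import Fraction

            q = Fraction(int(rng.integers(-20, 21)), int(rng.integers(1, 5)))
            try:
                gap = rational_identity_gap(rec, q, idc["N"])
            except PoleError:
                continue
            worst_gap = max(worst_gap, float(gap))
            checked += 1
    props.append({"property": "continued_fraction_rational_identity",
                  "samples": checked, "max_deviation": worst_gap,
                  "passed": worst_gap == 0.0})

    # 3. quantization spectrum vs dense oracle (binary choice)
    spc = cfg["spectrum"]
    worst_spec = 0.0
    for k in range(spc["models"]):
        N = int(rng.choice(spc["N"]))
        model = BinaryChoiceModel(N=N, eps1=round(rng.uniform(0.2, 3), 3),
                                  eps2=round(rng.uniform(0.2, 3), 3),
                                  mu1=round(rng.uniform(0.2, 3), 3),
                                  mu2=round(rng.uniform(0.2, 3), 3))
        lam = eigen_spectrum(model).rates
        ref = dense_spectrum_oracle(binary_choice_generator(model))
        worst_spec = max(worst_spec, float(np.abs(lam - ref).max()))
    props.append({"property": "quantization_roots_match_dense_spectrum",
                  "samples": spc["models"], "max_deviation": worst_spec,
                  "passed": worst_spec < 1e-6})

    # 4. Heun ODE residual
    hc = cfg["heun"]
    worst_res = 0.0
    for k in range(hc["draws"]):
        kind = "confluent" if k % 2 else "general"
        params = random_heun_params(FixtureSpec("heun_params", seed=seed * 3000 + k,
                                                extra={"kind": kind}))
        series = heun_series(params, hc["order"], method="forward")
        from .heun import convergence_radius

        r = 0.2 * convergence_radius(params)
        worst_res = max(worst_res, ode_residual(series, [r, -r, r * 1j]))
    props.append({"property": "heun_series_annihilates_ode",
                  "samples": hc["draws"], "max_deviation": worst_res,
                  "passed": worst_res < 1e-10})

    # 5. spectral evolution vs matrix exponential
    ec = cfg["evolve"]
    worst_evolve = 0.0
    for k in range(ec["models"]):
        model = BinaryChoiceModel(N=ec["N"], eps1=rng.uniform(0.5, 2), eps2=rng.uniform(0.5, 2),
                                  mu1=rng.uniform(0.2, 1), mu2=rng.uniform(0.2, 1))
        g = binary_choice_generator(model)
        P0 = np.zeros(ec["N"] + 1)
        P0[0] = 1.0
        sol = evolve(g, P0, ec["times"])
        for j, t in enumerate(ec["times"]):
            ref = matrix_exponential_oracle(g, P0, t)
            worst_evolve = max(worst_evolve, float(np.abs(sol[:, j] - ref).max()))
    props.append({"property": "spectral_evolution_matches_expm",
                  "samples": ec["models"] * len(ec["times"]), "max_deviation": worst_evolve,
                  "passed": worst_evolve < 1e-8})

    report = {
        "seed": seed,
        "config": cfg,
        "properties": props,
        "passed": all(p["passed"] for p in props),
    }
    return report
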