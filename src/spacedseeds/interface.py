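"""Command-line interface: thin click wrappers over the library modules.

Subcommands mirror the analysis stages: ``hits``, ``coeffs``, ``sensitivity``,
``lossless``, ``dominant``, ``pareto``, ``design``, ``asym``.  Structured
results go to JSON (exact rationals serialized as "num/den" strings, never
floats), tabular exports to TSV.  Every run can write a manifest sufficient
to reproduce it.
"""

from __future__ import annotations

import json
import logging
import sys
from fractions import Fraction
from pathlib import Path

import click

from . import __version__
from .asymptotics import build_substochastic, lambda_beta
from .counting import count_coefficients
from .design import SearchSpec, enumerate_seeds, run_pipeline
from .dominance import dominant_filter
from .models import (
    bernoulli_sensitivity,
    dirac,
    heaviside,
    hit_integration,
    lossless_from_coefficients,
    lossless_tropical,
)
from .pareto import CONTINUOUS_MODELS, DISCRETE_MODELS, pareto_continuous, pareto_discrete
from .seedcore import Alignment, SeedSet, hit_positions, parse_seed_set, read_seed_file

log = logging.getLogger("spacedseeds")


def _emit(payload: dict, output: str | None) -> None:
    text = json.dumps(payload, indent=2, sort_keys=True)
    if output:
        Path(output).write_text(text + "\n")
    else:
        click.echo(text)


def _rat(x: Fraction) -> str:
    return f"{x.numerator}/{x.denominator}"


@click.group()
@click.version_option(__version__)
@click.option("--log-level", default="WARNING", show_default=True)
def main(log_level: str) -> None:
    """Spaced-seed selection: dominance filtering and parameter-free sensitivity."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.WARNING))


@main.command()
@click.option("--seed", "seed_text", required=True, help="comma-separated seed patterns")
@click.option("--alignment", required=True, help="binary match/mismatch string")
def hits(seed_text: str, alignment: str) -> None:
    """Report hit positions of each seed on a binary alignment."""
    ss = parse_seed_set(seed_text)
    aln = Alignment(alignment)
    per_seed = {str(s): sorted(hit_positions(s, aln)) for s in ss}
    _emit(
        {
            "seedset": str(ss),
            "alignment": alignment,
            "hit_positions": per_seed,
            "hits": any(per_seed.values()),
        },
        None,
    )


@main.command()
@click.option("--seed", "seed_text", required=True)
@click.option("--length", "-l", type=int, required=True)
@click.option("--tsv", "tsv_path", default=None, help="also write the coefficient TSV here")
@click.option("--output", default=None)
def coeffs(seed_text: str, length: int, tsv_path: str | None, output: str | None) -> None:
    """Coefficient vector c(m): detected alignments per match count."""
    ss = parse_seed_set(seed_text)
    vec = count_coefficients(ss, length)
    if tsv_path:
        Path(tsv_path).write_text(vec.to_tsv())
    _emit(
        {
            "seedset": str(ss),
            "l": length,
            "coefficients": list(vec.coefficients),
            "total_accepted": vec.total_accepted,
        },
        output,
    )


@main.command()
@click.option("--seed", "seed_text", required=True)
@click.option("--length", "-l", type=int, required=True)
@click.option(
    "--model",
    type=click.Choice(["bernoulli", "hit_integration", "dirac", "heaviside"]),
    default="bernoulli",
    show_default=True,
)
@click.option("--p", type=str, default=None, help="match probability (Bernoulli)")
@click.option("--pa", type=str, default=None)
@click.option("--pb", type=str, default=None)
@click.option("--m", type=int, default=None, help="match count (Dirac)")
@click.option("--ma", type=int, default=None)
@click.option("--mb", type=int, default=None)
@click.option("--output", default=None)
def sensitivity(seed_text, length, model, p, pa, pb, m, ma, mb, output) -> None:
    """Evaluate one of the four sensitivity models."""
    ss = parse_seed_set(seed_text)
    vec = count_coefficients(ss, length)
    params: dict = {}
    if model == "bernoulli":
        if p is None:
            raise click.UsageError("bernoulli needs --p")
        value = bernoulli_sensitivity(vec, Fraction(p))
        params = {"p": p}
    elif model == "hit_integration":
        if pa is None or pb is None:
            raise click.UsageError("hit_integration needs --pa and --pb")
        value = hit_integration(vec, Fraction(pa), Fraction(pb))
        params = {"pa": pa, "pb": pb}
    elif model == "dirac":
        if m is None:
            raise click.UsageError("dirac needs --m")
        value = dirac(vec, m)
        params = {"m": m}
    else:
        if ma is None or mb is None:
            raise click.UsageError("heaviside needs --ma and --mb")
        value = heaviside(vec, ma, mb)
        params = {"ma": ma, "mb": mb}
    _emit(
        {
            "seedset": str(ss),
            "l": length,
            "model": model,
            "params": params,
            "value": _rat(value),
            "value_float": float(value),
        },
        output,
    )


@main.command()
@click.option("--seed", "seed_text", required=True)
@click.option("--length", "-l", type=int, required=True)
@click.option("--k", type=int, required=True, help="mismatch budget")
@click.option("--output", default=None)
def lossless(seed_text: str, length: int, k: int, output: str | None) -> None:
    """(l, k)-losslessness via the tropical DP (with witness on failure)."""
    ss = parse_seed_set(seed_text)
    ok, witness = lossless_tropical(ss, length, k)
    vec = count_coefficients(ss, length)
    _emit(
        {
            "seedset": str(ss),
            "l": length,
            "k": k,
            "lossless": ok,
            "lossless_coefficient_route": lossless_from_coefficients(vec, k),
            "witness": witness,
        },
        output,
    )


@main.command()
@click.option("--seed-file", type=click.Path(exists=True), default=None)
@click.option("--weight", "-w", type=int, default=None)
@click.option("--max-span", type=int, default=None)
@click.option("--length", "-l", type=int, required=True)
@click.option("--tsv", "tsv_path", default=None)
@click.option("--output", default=None)
def dominant(seed_file, weight, max_span, length, tsv_path, output) -> None:
    """Stage 1: dominant-set filter over a seed file or an enumeration class."""
    if seed_file:
        sets = read_seed_file(seed_file)
    elif weight:
        cap = max_span if max_span else 2 * weight
        sets = [SeedSet((s,)) for s in enumerate_seeds(weight, cap)]
    else:
        raise click.UsageError("need --seed-file or --weight")
    cands = [(ss, count_coefficients(ss, length)) for ss in sets]
    classes = dominant_filter(cands)
    kept = {str(m): i for i, c in enumerate(classes) for m in c.members}
    log.info("dominant filter: %d candidates -> %d classes", len(cands), len(classes))
    if tsv_path:
        rows = ["seed_set\tl\tis_dominant\tclass_id"]
        for ss, _ in cands:
            key = str(ss)
            rows.append(f"{key}\t{length}\t{int(key in kept)}\t{kept.get(key, '')}")
        Path(tsv_path).write_text("\n".join(rows) + "\n")
    _emit(
        {
            "l": length,
            "n_candidates": len(cands),
            "n_dominant_classes": len(classes),
            "n_dominant_seeds": sum(len(c.members) for c in classes),
            "classes": [[str(m) for m in c.members] for c in classes],
        },
        output,
    )


@main.command()
@click.option("--seed-file", type=click.Path(exists=True), required=True)
@click.option("--length", "-l", type=int, required=True)
@click.option(
    "--model",
    type=click.Choice(list(CONTINUOUS_MODELS + DISCRETE_MODELS)),
    default="bernoulli",
    show_default=True,
)
@click.option("--output", default=None)
def pareto(seed_file, length, model, output) -> None:
    """Stage 2: parameter-free optimal seeds among the dominant candidates."""
    sets = read_seed_file(seed_file)
    cands = [(ss, count_coefficients(ss, length)) for ss in sets]
    reps = [(c.representative, c.vector) for c in dominant_filter(cands)]
    if model in CONTINUOUS_MODELS:
        res = pareto_continuous(reps, model)
    else:
        res = pareto_discrete(reps, model)
    _emit(res.to_json_dict(), output)


@main.command()
@click.option("--n", type=int, default=1, show_default=True)
@click.option("--weight", "-w", type=int, required=True)
@click.option("--max-span", type=int, default=None)
@click.option("--lengths", default=None, help="range A:B (inclusive)")
@click.option(
    "--mode", type=click.Choice(["exhaustive", "hillclimb"]), default="exhaustive",
    show_default=True,
)
@click.option("--rng-seed", type=int, default=0, show_default=True)
@click.option("--restarts", type=int, default=32, show_default=True)
@click.option("--models", default="", help="comma-separated model list")
@click.option("--output", default=None)
def design(n, weight, max_span, lengths, mode, rng_seed, restarts, models, output) -> None:
    """End-to-end two-stage pipeline with a reproducibility manifest."""
    if lengths:
        a, b = (int(t) for t in lengths.split(":"))
        lens: tuple[int, ...] = tuple(range(a, b + 1))
    else:
        lens = ()
    spec = SearchSpec(
        n=n, weight=weight, max_span=max_span, lengths=lens, mode=mode,
        rng_seed=rng_seed, restarts=restarts,
    )
    model_list = [m for m in models.split(",") if m]
    result = run_pipeline(spec, model_list)
    payload = {
        "manifest": result.manifest() | {"version": __version__},
        "dominant": {
            str(l): [[str(m) for m in c.members] for c in cls]
            for l, cls in result.dominant.items()
        },
        "pareto": {
            str(l): {m: r.to_json_dict() for m, r in per.items()}
            for l, per in result.pareto.items()
        },
    }
    _emit(payload, output)


@main.command()
@click.option("--seed", "seed_text", required=True)
@click.option("--p", type=float, default=0.7, show_default=True)
@click.option("--output", default=None)
def asym(seed_text: str, p: float, output: str | None) -> None:
    """Asymptotic no-hit decay: Perron eigenvalue lambda and prefactor beta."""
    ss = parse_seed_set(seed_text)
    system = build_substochastic(ss, p)
    lam, beta = lambda_beta(system)
    _emit(
        {
            "seedset": str(ss),
            "p": p,
            "states": system.n_states,
            "lambda": round(lam, 5),
            "beta": round(beta, 5),
        },
        output,
    )


if __name__ == "__main__":
    main()
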