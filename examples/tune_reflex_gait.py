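"""Tune the reflex controller with the seeded (mu, lambda) ES.

This is the script (run with a larger budget) that produced the shipped
data/reflex_walker.json. The small budget here only demonstrates the search
loop; expect modest improvement, not a finished gait.
"""

import numpy as np

import planargait as pg
from planargait.control import (PARAM_BOUNDS, PARAM_DEFAULTS, ReflexParams,
                                ReflexState, reflex_policy, search_params)


def episode_fitness(values, steps=400, seed=2):
    """Time alive + forward progress + footstep count."""
    try:
        params = pg.ReflexParams(values)
    except ValueError:
        return -100.0
    env = pg.PlanarWalkEnv(pg.EpisodeConfig(seed=seed, mode="planar-18",
                                            max_steps=steps))
    obs = env.reset()
    state = ReflexState()
    done, i = False, 0
    try:
        while not done:
            action, state = reflex_policy(obs, params, state,
                                          mode="planar-18")
            obs, _, done, info = env.step(action)
            i += 1
    except FloatingPointError:
        return -50.0
    result = info["result"]
    return (i * 0.01 + 1.5 * env.state.q[0]
            + 0.5 * len(result.footsteps))


best, log = search_params(episode_fitness, PARAM_BOUNDS, budget=48,
                          rng=0, population=8, x0=PARAM_DEFAULTS,
                          sigma0=0.15)
print(f"evaluations: {log['evals']}, best fitness: {log['best_f']:.2f}")
print("best-so-far trace:", [round(t, 2) for t in log["trace"]])
print("tuned parameters:")
for name, v in ReflexParams(best).as_dict().items():
    print(f"  {name:18s} {v:.4f}")
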