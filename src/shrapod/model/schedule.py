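"""Learning-rate schedule: quartic warmup ramp to the base rate.

During the warmup period the rate follows
``base_lr × (iteration / warmup_iters)^4``, reaching exactly
``base_lr`` at the end of warmup.  After warmup the rate is constant by
default; an optional mirrored quartic decay
(``base_lr × (warmup_iters / iteration)^4``) can be switched on, for
the reading under which the ramp expression governs a post-warmup
slowdown instead.
"""

from __future__ import annotations

__all__ = ["lr_schedule"]


def lr_schedule(iteration: int, base_lr: float = 0.001,
                warmup_iters: int = 1000,
                post_warmup_decay: bool = False) -> float:
    """Learning rate at a 1-based training iteration."""
    if iteration < 1:
        raise ValueError("iteration is 1-based")
    if iteration <= warmup_iters:
        return base_lr * (iteration / warmup_iters) ** 4
    if post_warmup_decay:
        return base_lr * (warmup_iters / iteration) ** 4
    return base_lr
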