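"""The Becker-deGroot-Marschak (BDM) auction mechanism.

A bidder states an integer bid in [0, 150] monetary units (MU) for a
product; a capsule price is drawn uniformly from {1, ..., 150}.  The bidder
purchases at the capsule price iff the bid is greater than or equal to it,
paying the *capsule* price, not the bid; otherwise they pay nothing and
keep the full 150 MU endowment.  Under this rule the expected payoff of a
bidder whose subjective product value is v is maximized by bidding v
(truthful revelation), which :func:`optimal_bid` demonstrates by exhaustive
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ENDOWMENT",
    "CAPSULE_MIN",
    "CAPSULE_MAX",
    "AuctionOutcome",
    "bdm_outcome",
    "winning_set",
    "expected_payoff",
    "optimal_bid",
]

ENDOWMENT = 150
CAPSULE_MIN = 1
CAPSULE_MAX = 150


@dataclass(frozen=True)
class AuctionOutcome:
    """Result of one BDM realization.

    ``payment`` equals the capsule price on purchase and 0 otherwise;
    ``final_balance`` is the endowment minus the payment, so payment and
    balance always sum to the 150 MU endowment.
    """

    bid: int
    capsule_price: int
    purchased: bool
    payment: int
    final_balance: int
    product_value: int | None = None


def _check_bid(bid) -> int:
    if bid != int(bid) or not 0 <= bid <= ENDOWMENT:
        raise ValueError(f"bid must be an integer in [0, {ENDOWMENT}], got {bid!r}")
    return int(bid)


def _check_capsule(capsule_price) -> int:
    if capsule_price != int(capsule_price) or not CAPSULE_MIN <= capsule_price <= CAPSULE_MAX:
        raise ValueError(
            f"capsule price must be an integer in [{CAPSULE_MIN}, {CAPSULE_MAX}], "
            f"got {capsule_price!r}"
        )
    return int(capsule_price)


def bdm_outcome(bid, capsule_price, product_value=None) -> AuctionOutcome:
    """Realize one auction: purchase iff ``bid >= capsule_price``."""
    bid = _check_bid(bid)
    capsule_price = _check_capsule(capsule_price)
    purchased = bid >= capsule_price
    payment = capsule_price if purchased else 0
    return AuctionOutcome(
        bid=bid,
        capsule_price=capsule_price,
        purchased=purchased,
        payment=payment,
        final_balance=ENDOWMENT - payment,
        product_value=product_value,
    )


def winning_set(bid) -> set[int]:
    """Capsule values at which the bid wins: {1, ..., bid} (empty for bid 0)."""
    bid = _check_bid(bid)
    return set(range(CAPSULE_MIN, bid + 1))


def _payoff_score(bid: int, value: int) -> int:
    # 150 * (expected payoff - 150): integer-exact surplus sum over capsules
    return bid * value - bid * (bid + 1) // 2


def expected_payoff(bid, product_value) -> float:
    """Expected final wealth (balance + product value if purchased), in MU.

    Exact: the sum over the 150 equiprobable capsule prices is carried out
    in integer arithmetic before the single division by 150.
    """
    bid = _check_bid(bid)
    value = _check_bid(product_value)
    return ENDOWMENT + _payoff_score(bid, value) / CAPSULE_MAX


def optimal_bid(product_value) -> int:
    """Brute-force argmax of expected payoff over all 151 integer bids.

    Bidding v-1 and v tie exactly (purchasing at capsule price v yields zero
    surplus); the tie is resolved toward the value itself, exhibiting
    truthful bidding as the optimum.
    """
    value = _check_bid(product_value)
    scores = [_payoff_score(b, value) for b in range(ENDOWMENT + 1)]
    best = max(scores)
    winners = [b for b, sc in enumerate(scores) if sc == best]
    if value in winners:
        return value
    return min(winners, key=lambda b: (abs(b - value), b))  # pragma: no cover
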