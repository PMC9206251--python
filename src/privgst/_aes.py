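"""Minimal AES-128 with CBC mode, pure Python.

No AES provider ships with the deployment environment, and the only use
here is deterministic, block-aligned encryption of fixed-size digests, so a
compact table-driven implementation suffices.  Encryption uses the standard
T-table formulation for speed; decryption (rare: only researcher-side
reference tokens) uses the straightforward inverse cipher.

Correctness is pinned to the FIPS-197 known-answer vectors in the test
suite.  This module deliberately implements nothing beyond ECB block
primitives and CBC over block-aligned input (no padding: digests are whole
blocks by construction).
"""

from __future__ import annotations

from typing import List

__all__ = ["aes_cbc_encrypt", "aes_cbc_decrypt", "expand_key", "BLOCK"]

BLOCK = 16

_SBOX = [
    0x63, 0x7C, 0x77, 0x7B, 0xF2, 0x6B, 0x6F, 0xC5, 0x30, 0x01, 0x67, 0x2B,
    0xFE, 0xD7, 0xAB, 0x76, 0xCA, 0x82, 0xC9, 0x7D, 0xFA, 0x59, 0x47, 0xF0,
    0xAD, 0xD4, 0xA2, 0xAF, 0x9C, 0xA4, 0x72, 0xC0, 0xB7, 0xFD, 0x93, 0x26,
    0x36, 0x3F, 0xF7, 0xCC, 0x34, 0xA5, 0xE5, 0xF1, 0x71, 0xD8, 0x31, 0x15,
    0x04, 0xC7, 0x23, 0xC3, 0x18, 0x96, 0x05, 0x9A, 0x07, 0x12, 0x80, 0xE2,
    0xEB, 0x27, 0xB2, 0x75, 0x09, 0x83, 0x2C, 0x1A, 0x1B, 0x6E, 0x5A, 0xA0,
    0x52, 0x3B, 0xD6, 0xB3, 0x29, 0xE3, 0x2F, 0x84, 0x53, 0xD1, 0x00, 0xED,
    0x20, 0xFC, 0xB1, 0x5B, 0x6A, 0xCB, 0xBE, 0x39, 0x4A, 0x4C, 0x58, 0xCF,
    0xD0, 0xEF, 0xAA, 0xFB, 0x43, 0x4D, 0x33, 0x85, 0x45, 0xF9, 0x02, 0x7F,
    0x50, 0x3C, 0x9F, 0xA8, 0x51, 0xA3, 0x40, 0x8F, 0x92, 0x9D, 0x38, 0xF5,
    0xBC, 0xB6, 0xDA, 0x21, 0x10, 0xFF, 0xF3, 0xD2, 0xCD, 0x0C, 0x13, 0xEC,
    0x5F, 0x97, 0x44, 0x17, 0xC4, 0xA7, 0x7E, 0x3D, 0x64, 0x5D, 0x19, 0x73,
    0x60, 0x81, 0x4F, 0xDC, 0x22, 0x2A, 0x90, 0x88, 0x46, 0xEE, 0xB8, 0x14,
    0xDE, 0x5E, 0x0B, 0xDB, 0xE0, 0x32, 0x3A, 0x0A, 0x49, 0x06, 0x24, 0x5C,
    0xC2, 0xD3, 0xAC, 0x62, 0x91, 0x95, 0xE4, 0x79, 0xE7, 0xC8, 0x37, 0x6D,
    0x8D, 0xD5, 0x4E, 0xA9, 0x6C, 0x56, 0xF4, 0xEA, 0x65, 0x7A, 0xAE, 0x08,
    0xBA, 0x78, 0x25, 0x2E, 0x1C, 0xA6, 0xB4, 0xC6, 0xE8, 0xDD, 0x74, 0x1F,
    0x4B, 0xBD, 0x8B, 0x8A, 0x70, 0x3E, 0xB5, 0x66, 0x48, 0x03, 0xF6, 0x0E,
    0x61, 0x35, 0x57, 0xB9, 0x86, 0xC1, 0x1D, 0x9E, 0xE1, 0xF8, 0x98, 0x11,
    0x69, 0xD9, 0x8E, 0x94, 0x9B, 0x1E, 0x87, 0xE9, 0xCE, 0x55, 0x28, 0xDF,
    0x8C, 0xA1, 0x89, 0x0D, 0xBF, 0xE6, 0x42, 0x68, 0x41, 0x99, 0x2D, 0x0F,
    0xB0, 0x54, 0xBB, 0x16,
]

_INV_SBOX = [0] * 256
for _i, _v in enumerate(_SBOX):
    _INV_SBOX[_v] = _i


def _xtime(a: int) -> int:
    a <<= 1
    if a & 0x100:
        a ^= 0x11B
    return a & 0xFF


def _gmul(a: int, b: int) -> int:
    out = 0
    while b:
        if b & 1:
            out ^= a
        a = _xtime(a)
        b >>= 1
    return out


# T-tables for the encryption round function.
_T0 = []
_T1 = []
_T2 = []
_T3 = []
for _x in range(256):
    _s = _SBOX[_x]
    _w = (_gmul(_s, 2) << 24) | (_s << 16) | (_s << 8) | _gmul(_s, 3)
    _T0.append(_w)
    _T1.append(((_w >> 8) | (_w << 24)) & 0xFFFFFFFF)
    _T2.append(((_w >> 16) | (_w << 16)) & 0xFFFFFFFF)
    _T3.append(((_w >> 24) | (_w << 8)) & 0xFFFFFFFF)

_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


def expand_key(key: bytes) -> List[int]:
    """AES-128 key schedule: 44 32-bit words."""
    if len(key) != 16:
        raise ValueError(f"AES-128 key must be 16 bytes, got {len(key)}")
    words = [int.from_bytes(key[i : i + 4], "big") for i in range(0, 16, 4)]
    for i in range(4, 44):
        temp = words[i - 1]
        if i % 4 == 0:
            temp = ((temp << 8) | (temp >> 24)) & 0xFFFFFFFF  # RotWord
            temp = (
                (_SBOX[(temp >> 24) & 0xFF] << 24)
                | (_SBOX[(temp >> 16) & 0xFF] << 16)
                | (_SBOX[(temp >> 8) & 0xFF] << 8)
                | _SBOX[temp & 0xFF]
            )
            temp ^= _RCON[i // 4 - 1] << 24
        words.append(words[i - 4] ^ temp)
    return words


def _encrypt_block(block: bytes, rk: List[int]) -> bytes:
    c0 = int.from_bytes(block[0:4], "big") ^ rk[0]
    c1 = int.from_bytes(block[4:8], "big") ^ rk[1]
    c2 = int.from_bytes(block[8:12], "big") ^ rk[2]
    c3 = int.from_bytes(block[12:16], "big") ^ rk[3]
    for rnd in range(1, 10):
        base = rnd * 4
        n0 = (_T0[(c0 >> 24) & 0xFF] ^ _T1[(c1 >> 16) & 0xFF]
              ^ _T2[(c2 >> 8) & 0xFF] ^ _T3[c3 & 0xFF] ^ rk[base])
        n1 = (_T0[(c1 >> 24) & 0xFF] ^ _T1[(c2 >> 16) & 0xFF]
              ^ _T2[(c3 >> 8) & 0xFF] ^ _T3[c0 & 0xFF] ^ rk[base + 1])
        n2 = (_T0[(c2 >> 24) & 0xFF] ^ _T1[(c3 >> 16) & 0xFF]
              ^ _T2[(c0 >> 8) & 0xFF] ^ _T3[c1 & 0xFF] ^ rk[base + 2])
        n3 = (_T0[(c3 >> 24) & 0xFF] ^ _T1[(c0 >> 16) & 0xFF]
              ^ _T2[(c1 >> 8) & 0xFF] ^ _T3[c2 & 0xFF] ^ rk[base + 3])
        c0, c1, c2, c3 = n0, n1, n2, n3
    # final round: SubBytes + ShiftRows + AddRoundKey, no MixColumns
    out = bytearray(16)
    cols = (c0, c1, c2, c3)
    for i in range(4):
        out[4 * i + 0] = _SBOX[(cols[i] >> 24) & 0xFF]
        out[4 * i + 1] = _SBOX[(cols[(i + 1) % 4] >> 16) & 0xFF]
        out[4 * i + 2] = _SBOX[(cols[(i + 2) % 4] >> 8) & 0xFF]
        out[4 * i + 3] = _SBOX[cols[(i + 3) % 4] & 0xFF]
    for i in range(4):
        w = rk[40 + i]
        out[4 * i + 0] ^= (w >> 24) & 0xFF
        out[4 * i + 1] ^= (w >> 16) & 0xFF
        out[4 * i + 2] ^= (w >> 8) & 0xFF
        out[4 * i + 3] ^= w & 0xFF
    return bytes(out)


def _decrypt_block(block: bytes, rk: List[int]) -> bytes:
    state = [[block[r + 4 * c] for c in range(4)] for r in range(4)]

    def add_round_key(rnd):
        for c in range(4):
            w = rk[rnd * 4 + c]
            state[0][c] ^= (w >> 24) & 0xFF
            state[1][c] ^= (w >> 16) & 0xFF
            state[2][c] ^= (w >> 8) & 0xFF
            state[3][c] ^= w & 0xFF

    def inv_shift_rows():
        for r in range(1, 4):
            state[r] = state[r][-r:] + state[r][:-r]

    def inv_sub_bytes():
        for r in range(4):
            for c in range(4):
                state[r][c] = _INV_SBOX[state[r][c]]

    def inv_mix_columns():
        for c in range(4):
            a = [state[r][c] for r in range(4)]
            state[0][c] = (_gmul(a[0], 14) ^ _gmul(a[1], 11)
                           ^ _gmul(a[2], 13) ^ _gmul(a[3], 9))
            state[1][c] = (_gmul(a[0], 9) ^ _gmul(a[1], 14)
                           ^ _gmul(a[2], 11) ^ _gmul(a[3], 13))
            state[2][c] = (_gmul(a[0], 13) ^ _gmul(a[1], 9)
                           ^ _gmul(a[2], 14) ^ _gmul(a[3], 11))
            state[3][c] = (_gmul(a[0], 11) ^ _gmul(a[1], 13)
                           ^ _gmul(a[2], 9) ^ _gmul(a[3], 14))

    add_round_key(10)
    for rnd in range(9, 0, -1):
        inv_shift_rows()
        inv_sub_bytes()
        add_round_key(rnd)
        inv_mix_columns()
    inv_shift_rows()
    inv_sub_bytes()
    add_round_key(0)
    return bytes(state[r][c] for c in range(4) for r in range(4))


def aes_cbc_encrypt(key: bytes, iv: bytes, plaintext: bytes) -> bytes:
    """CBC over block-aligned plaintext (no padding; output size = input)."""
    if len(iv) != BLOCK:
        raise ValueError(f"IV must be {BLOCK} bytes")
    if len(plaintext) % BLOCK:
        raise ValueError("plaintext length must be a multiple of 16")
    rk = expand_key(key)
    out = bytearray()
    prev = iv
    for i in range(0, len(plaintext), BLOCK):
        block = bytes(a ^ b for a, b in zip(plaintext[i : i + BLOCK], prev))
        prev = _encrypt_block(block, rk)
        out += prev
    return bytes(out)


def aes_cbc_decrypt(key: bytes, iv: bytes, ciphertext: bytes) -> bytes:
    if len(iv) != BLOCK:
        raise ValueError(f"IV must be {BLOCK} bytes")
    if len(ciphertext) % BLOCK:
        raise ValueError("ciphertext length must be a multiple of 16")
    rk = expand_key(key)
    out = bytearray()
    prev = iv
    for i in range(0, len(ciphertext), BLOCK):
        block = ciphertext[i : i + BLOCK]
        out += bytes(a ^ b for a, b in zip(_decrypt_block(block, rk), prev))
        prev = block
    return bytes(out)
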