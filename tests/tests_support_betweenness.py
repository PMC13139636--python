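"""Brute-force betweenness by shortest-path enumeration (test oracle)."""

import collections
import itertools


def brute_betweenness(g):
    nodes = list(g.nodes())
    adj = {v: set(g.neighbors(v)) for v in nodes}
    bw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = {s: 0}
        queue = collections.deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        if t not in dist:
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    extend(path + [w])

        extend([s])
        for p in paths:
            for v in p[1:-1]:
                bw[v] += 1.0 / len(paths)
    return bw
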