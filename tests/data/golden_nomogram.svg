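<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="820" height="320" viewBox="0 0 820 320">
<style>line.axis{stroke:#000;stroke-width:1}line.total{stroke:#444;stroke-width:1}text{font-family:Helvetica,Arial,sans-serif;font-size:10px;fill:#000}text.axis-label{font-size:11px}text.title{font-size:14px;font-weight:bold}</style>
<text x="410" y="20" text-anchor="middle" class="title">Toy model</text>
<text x="140" y="54" text-anchor="end" class="axis-label">Points</text>
<line x1="150" y1="50" x2="780" y2="50" class="axis"/>
<line x1="150" y1="44" x2="150" y2="50" class="axis"/>
<text x="150" y="41" text-anchor="middle" class="tick-label">0</text>
<line x1="213" y1="44" x2="213" y2="50" class="axis"/>
<text x="213" y="41" text-anchor="middle" class="tick-label">10</text>
<line x1="276" y1="44" x2="276" y2="50" class="axis"/>
<text x="276" y="41" text-anchor="middle" class="tick-label">20</text>
<line x1="339" y1="44" x2="339" y2="50" class="axis"/>
<text x="339" y="41" text-anchor="middle" class="tick-label">30</text>
<line x1="402" y1="44" x2="402" y2="50" class="axis"/>
<text x="402" y="41" text-anchor="middle" class="tick-label">40</text>
<line x1="465" y1="44" x2="465" y2="50" class="axis"/>
<text x="465" y="41" text-anchor="middle" class="tick-label">50</text>
<line x1="528" y1="44" x2="528" y2="50" class="axis"/>
<text x="528" y="41" text-anchor="middle" class="tick-label">60</text>
<line x1="591" y1="44" x2="591" y2="50" class="axis"/>
<text x="591" y="41" text-anchor="middle" class="tick-label">70</text>
<line x1="654" y1="44" x2="654" y2="50" class="axis"/>
<text x="654" y="41" text-anchor="middle" class="tick-label">80</text>
<line x1="717" y1="44" x2="717" y2="50" class="axis"/>
<text x="717" y="41" text-anchor="middle" class="tick-label">90</text>
<line x1="780" y1="44" x2="780" y2="50" class="axis"/>
<text x="780" y="41" text-anchor="middle" class="tick-label">100</text>
<text x="140" y="106" text-anchor="end" class="axis-label">x1</text>
<line x1="150" y1="102" x2="780" y2="102" class="axis"/>
<line x1="150" y1="96" x2="150" y2="102" class="axis"/>
<text x="150" y="93" text-anchor="middle" class="tick-label">0</text>
<line x1="276" y1="96" x2="276" y2="102" class="axis"/>
<text x="276" y="93" text-anchor="middle" class="tick-label">1</text>
<line x1="402" y1="96" x2="402" y2="102" class="axis"/>
<text x="402" y="93" text-anchor="middle" class="tick-label">2</text>
<line x1="528" y1="96" x2="528" y2="102" class="axis"/>
<text x="528" y="93" text-anchor="middle" class="tick-label">3</text>
<line x1="654" y1="96" x2="654" y2="102" class="axis"/>
<text x="654" y="93" text-anchor="middle" class="tick-label">4</text>
<line x1="780" y1="96" x2="780" y2="102" class="axis"/>
<text x="780" y="93" text-anchor="middle" class="tick-label">5</text>
<text x="140" y="158" text-anchor="end" class="axis-label">x2</text>
<line x1="150" y1="154" x2="402" y2="154" class="axis"/>
<line x1="150" y1="148" x2="150" y2="154" class="axis"/>
<text x="150" y="145" text-anchor="middle" class="tick-label">0</text>
<line x1="200.4" y1="148" x2="200.4" y2="154" class="axis"/>
<text x="200.4" y="145" text-anchor="middle" class="tick-label">0.8</text>
<line x1="250.8" y1="148" x2="250.8" y2="154" class="axis"/>
<text x="250.8" y="145" text-anchor="middle" class="tick-label">1.6</text>
<line x1="301.2" y1="148" x2="301.2" y2="154" class="axis"/>
<text x="301.2" y="145" text-anchor="middle" class="tick-label">2.4</text>
<line x1="351.6" y1="148" x2="351.6" y2="154" class="axis"/>
<text x="351.6" y="145" text-anchor="middle" class="tick-label">3.2</text>
<line x1="402" y1="148" x2="402" y2="154" class="axis"/>
<text x="402" y="145" text-anchor="middle" class="tick-label">4</text>
<text x="140" y="220" text-anchor="end" class="axis-label">Total points</text>
<line x1="150" y1="216" x2="780" y2="216" class="total"/>
<line x1="150" y1="210" x2="150" y2="216" class="total"/>
<text x="150" y="207" text-anchor="middle" class="tick-label">0</text>
<line x1="213" y1="210" x2="213" y2="216" class="total"/>
<text x="213" y="207" text-anchor="middle" class="tick-label">14</text>
<line x1="276" y1="210" x2="276" y2="216" class="total"/>
<text x="276" y="207" text-anchor="middle" class="tick-label">28</text>
<line x1="339" y1="210" x2="339" y2="216" class="total"/>
<text x="339" y="207" text-anchor="middle" class="tick-label">42</text>
<line x1="402" y1="210" x2="402" y2="216" class="total"/>
<text x="402" y="207" text-anchor="middle" class="tick-label">56</text>
<line x1="465" y1="210" x2="465" y2="216" class="total"/>
<text x="465" y="207" text-anchor="middle" class="tick-label">70</text>
<line x1="528" y1="210" x2="528" y2="216" class="total"/>
<text x="528" y="207" text-anchor="middle" class="tick-label">84</text>
<line x1="591" y1="210" x2="591" y2="216" class="total"/>
<text x="591" y="207" text-anchor="middle" class="tick-label">98</text>
<line x1="654" y1="210" x2="654" y2="216" class="total"/>
<text x="654" y="207" text-anchor="middle" class="tick-label">112</text>
<line x1="717" y1="210" x2="717" y2="216" class="total"/>
<text x="717" y="207" text-anchor="middle" class="tick-label">126</text>
<line x1="780" y1="210" x2="780" y2="216" class="total"/>
<text x="780" y="207" text-anchor="middle" class="tick-label">140</text>
<text x="140" y="272" text-anchor="end" class="axis-label">mean response (gaussian, identity link)</text>
<line x1="150" y1="268" x2="780" y2="268" class="total"/>
<line x1="150" y1="262" x2="150" y2="268" class="total"/>
<text x="150" y="259" text-anchor="middle" class="tick-label">0</text>
<line x1="240" y1="262" x2="240" y2="268" class="total"/>
<text x="240" y="259" text-anchor="middle" class="tick-label">1</text>
<line x1="330" y1="262" x2="330" y2="268" class="total"/>
<text x="330" y="259" text-anchor="middle" class="tick-label">2</text>
<line x1="420" y1="262" x2="420" y2="268" class="total"/>
<text x="420" y="259" text-anchor="middle" class="tick-label">3</text>
<line x1="510" y1="262" x2="510" y2="268" class="total"/>
<text x="510" y="259" text-anchor="middle" class="tick-label">4</text>
<line x1="600" y1="262" x2="600" y2="268" class="total"/>
<text x="600" y="259" text-anchor="middle" class="tick-label">5</text>
<line x1="690" y1="262" x2="690" y2="268" class="total"/>
<text x="690" y="259" text-anchor="middle" class="tick-label">6</text>
<line x1="780" y1="262" x2="780" y2="268" class="total"/>
<text x="780" y="259" text-anchor="middle" class="tick-label">7</text>
</svg>
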