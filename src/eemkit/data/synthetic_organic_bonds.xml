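<?xml version='1.0' encoding='UTF-8'?>
<ParameterSet Name="Synthetic-Organic-Bonds" Kappa="0.3588935301313918" Provenance="Synthetic bond-order-granularity set for small organic molecules; generated, not fitted.">
  <Element Symbol="C">
    <Bond Type="1" A="3.092058368565831" B="12.881429164747459"/>
    <Bond Type="2" A="7.145254930282217" B="6.828499468643789"/>
    <Bond Type="3" A="3.734539022805438" B="11.292573913170319"/>
  </Element>
  <Element Symbol="H">
    <Bond Type="1" A="3.8760993963376853" B="7.794545781008381"/>
  </Element>
  <Element Symbol="N">
    <Bond Type="1" A="6.207774581775448" B="9.509440024956426"/>
    <Bond Type="2" A="4.888439622452866" B="11.919865154731436"/>
    <Bond Type="3" A="4.633784575389137" B="13.678982708634562"/>
  </Element>
  <Element Symbol="O">
    <Bond Type="1" A="3.856754256235562" B="6.894460956200927"/>
    <Bond Type="2" A="3.5194363297594444" B="6.446968181692195"/>
    <Bond Type="3" A="7.532696693836639" B="11.190716912977804"/>
  </Element>
</ParameterSet>
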