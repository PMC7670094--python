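# epidermal lycopene per unit fraction (1/mm), relative scale
# SYNTHETIC approximation; substitute your own table for exact literature curves.
# wavelength_nm	mu_a_per_mm
450	24.8225
452	24.1066
454	23.3647
456	22.8983
458	22.9424
460	23.6126
462	24.8747
464	26.547
466	28.3339
468	29.8847
470	30.8659
472	31.0309
474	30.2716
476	28.6419
478	26.3483
480	23.7118
482	21.1103
484	18.9129
486	17.4204
488	16.8181
490	17.1499
492	18.3132
494	20.076
496	22.1127
498	24.0546
500	25.5468
502	26.3031
504	26.1491
506	25.0442
508	23.0792
510	20.4505
512	17.4182
514	14.257
516	11.2133
518	8.47419
520	6.15327
522	4.2929
524	2.87758
526	1.85325
528	1.14676
530	0.68177
532	0.389433
534	0.213725
536	0.112696
538	0.0570935
540	0.0277904
542	0.0129966
544	0.00583977
546	0.00252109
548	0.0010457
550	0.000416733
552	0.000159564
554	5.87004e-05
556	2.07479e-05
558	7.0459e-06
560	2.29893e-06
562	7.20684e-07
564	2.17066e-07
566	6.28155e-08
568	1.7465e-08
570	4.66553e-09
572	1.19746e-09
574	2.9529e-10
576	6.99623e-11
578	1.59261e-11
580	3.48322e-12
582	0
584	0
586	0
588	0
590	0
592	0
594	0
596	0
598	0
600	0
602	0
604	0
606	0
608	0
610	0
612	0
614	0
616	0
618	0
620	0
622	0
624	0
626	0
628	0
630	0
632	0
634	0
636	0
638	0
640	0
642	0
644	0
646	0
648	0
650	0
652	0
654	0
656	0
658	0
660	0
662	0
664	0
666	0
668	0
670	0
672	0
674	0
676	0
678	0
680	0
682	0
684	0
686	0
688	0
690	0
692	0
694	0
696	0
698	0
700	0
702	0
704	0
706	0
708	0
710	0
712	0
714	0
716	0
718	0
720	0
722	0
724	0
726	0
728	0
730	0
732	0
734	0
736	0
738	0
740	0
742	0
744	0
746	0
748	0
750	0
752	0
754	0
756	0
758	0
760	0
762	0
764	0
766	0
768	0
770	0
772	0
774	0
776	0
778	0
780	0
782	0
784	0
786	0
788	0
790	0
792	0
794	0
796	0
798	0
800	0
802	0
804	0
806	0
808	0
810	0
812	0
814	0
816	0
818	0
820	0
822	0
824	0
826	0
828	0
830	0
832	0
834	0
836	0
838	0
840	0
842	0
844	0
846	0
848	0
850	0
852	0
854	0
856	0
858	0
860	0
862	0
864	0
866	0
868	0
870	0
872	0
874	0
876	0
878	0
880	0
882	0
884	0
886	0
888	0
890	0
892	0
894	0
896	0
898	0
900	0
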